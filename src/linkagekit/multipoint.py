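"""Multi-locus pseudo-testcross analysis and genetic-map construction.

In a pseudo-testcross (multiply heterozygous parent x fully recessive
tester) every progeny phenotype reveals one gamete of the informative
parent.  Tracing each gamete allele back to a parental homolog yields a
crossover class (parental / single / double / triple, named by the
intervals involved); the recombination frequency of an interval is the
fraction of gametes that switch homolog origin across it, and the locus
order is searched over all distinct arrangements by multinomial likelihood.

Map distances come from the Kosambi function m = 25 ln[(1+2r)/(1-2r)]
(cM), which partially accounts for crossover interference, or from the
interference-free Haldane function m = -50 ln(1-2r).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genetic_model import (
    CountTable,
    GeneticsDomainError,
    PhasedGenotype,
    TraitModel,
    phenotype_of,
)
from .linkage_pairwise import RecombinationEstimate

__all__ = [
    "CrossoverClass",
    "LocusOrder",
    "MapDistance",
    "IntervalAnalysis",
    "OrderScore",
    "infer_gamete",
    "classify_crossovers",
    "interval_rfs",
    "search_order",
    "map_distance",
    "inverse_map_distance",
    "build_map",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossoverClass:
    """A haplotype-origin switch pattern under a given locus order."""

    switch_pattern: tuple[bool, ...]
    intervals: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.switch_pattern) != len(self.intervals):
            raise GeneticsDomainError("switch pattern / interval length mismatch")

    @property
    def n_switches(self) -> int:
        return sum(self.switch_pattern)

    @property
    def is_parental(self) -> bool:
        return self.n_switches == 0

    @property
    def label(self) -> str:
        if self.is_parental:
            return "parental"
        names = {1: "single", 2: "double", 3: "triple"}
        kind = names.get(self.n_switches, f"{self.n_switches}-fold")
        where = ", ".join(
            f"{a}-{b}" for (a, b), s in zip(self.intervals, self.switch_pattern) if s
        )
        return f"{kind} crossover ({where})"


@dataclass(frozen=True)
class LocusOrder:
    """An orientation-normalized locus order (an order equals its reverse)."""

    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise GeneticsDomainError(f"duplicate loci in order {self.loci}")
        if self.loci and self.loci[-1] < self.loci[0]:
            object.__setattr__(self, "loci", tuple(reversed(self.loci)))

    @property
    def intervals(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.loci, self.loci[1:]))

    def __str__(self) -> str:
        return "-".join(self.loci)

    @staticmethod
    def all_orders(loci: Sequence[str]) -> list["LocusOrder"]:
        """All distinct orders of ``loci`` (n!/2 of them; 12 for four loci)."""
        seen: dict[tuple[str, ...], LocusOrder] = {}
        for perm in itertools.permutations(loci):
            order = LocusOrder(perm)
            seen.setdefault(order.loci, order)
        return list(seen.values())


@dataclass(frozen=True)
class MapDistance:
    """A genetic map distance in centiMorgans with the function that made it."""

    cm: float
    function: str  # "kosambi" | "haldane"


@dataclass(frozen=True)
class IntervalAnalysis:
    """Interval recombination frequencies from classified crossover counts.

    ``end_to_end_percent`` is the sum of the interval RFs (the additive
    convention of the source tables); ``end_to_end_direct_percent`` is the
    plain switch frequency between the two terminal loci (always <= the
    sum), reported for comparison.  ``total`` is the denominator used; when
    a declared population size is supplied it may differ from the sum of
    the class counts (``count_sum``), in which case a warning is attached.
    """

    order: "LocusOrder"
    per_interval: tuple[RecombinationEstimate, ...]
    end_to_end_percent: float
    end_to_end_direct_percent: float
    parental_count: int
    total: int
    count_sum: int
    warnings: tuple[str, ...] = ()

    @property
    def parental_fraction(self) -> float:
        return self.parental_count / self.total


@dataclass(frozen=True)
class OrderScore:
    """One candidate locus order with its fit to the classified gametes."""

    order: LocusOrder
    log_likelihood: float
    interval_r: tuple[float, ...]  # fractions, per interval of ``order``
    n_multi_crossover: int
    map_length_cm: float


# ---------------------------------------------------------------------------
# Gamete inference and crossover classification
# ---------------------------------------------------------------------------


def infer_gamete(
    progeny_class: Sequence[str],
    loci: Sequence[str],
    tester: PhasedGenotype,
    models: Mapping[str, TraitModel],
) -> tuple[str, ...]:
    """The informative parent's gamete implied by one progeny phenotype.

    Requires the tester to be homozygous for its most recessive allele at
    every locus considered, which makes the gamete unique: the progeny
    phenotype at each locus is then the resolved label of the contributed
    allele over the recessive background.
    """
    if len(progeny_class) != len(loci):
        raise GeneticsDomainError(
            f"phenotype class {tuple(progeny_class)} does not match loci {tuple(loci)}"
        )
    gamete = []
    for label, locus in zip(progeny_class, loci):
        model = models[locus]
        t_a, t_b = tester.alleles_at(locus)
        if t_a != t_b or t_a != model.alleles[-1]:
            raise GeneticsDomainError(
                f"tester is not homozygous for the most recessive allele at "
                f"{locus!r} ({t_a}/{t_b}): pseudo-testcross gamete inference "
                "is not applicable"
            )
        candidates = [
            a for a in model.alleles if phenotype_of((a, t_a), model) == label
        ]
        if len(candidates) != 1:
            raise GeneticsDomainError(
                f"phenotype {label!r} at locus {locus!r} is consistent with "
                f"{len(candidates)} gamete alleles over a {t_a}/{t_a} tester"
            )
        gamete.append(candidates[0])
    return tuple(gamete)


def classify_crossovers(
    haplotype: Sequence[str],
    parent: PhasedGenotype,
    order: LocusOrder,
) -> CrossoverClass:
    """Classify a gamete haplotype by its origin switches under ``order``.

    ``haplotype`` carries one allele per locus of ``order`` (same order).
    Loci homozygous in the parent are uninformative and excluded with a
    warning; the remaining adjacent pairs define the intervals.
    """
    if len(haplotype) != len(order.loci):
        raise GeneticsDomainError(
            f"haplotype {tuple(haplotype)} does not match order {order}"
        )
    origins: list[int] = []
    kept: list[str] = []
    for allele, locus in zip(haplotype, order.loci):
        a, b = parent.alleles_at(locus)
        if a == b:
            warnings.warn(
                f"locus {locus!r} is homozygous in the parent; excluded from "
                "crossover classification",
                stacklevel=2,
            )
            continue
        if allele == a:
            origins.append(0)
        elif allele == b:
            origins.append(1)
        else:
            raise GeneticsDomainError(
                f"allele {allele!r} at {locus!r} traces to neither parental "
                f"homolog ({a}/{b})"
            )
        kept.append(locus)
    pattern = tuple(o1 != o2 for o1, o2 in zip(origins, origins[1:]))
    intervals = tuple(zip(kept, kept[1:]))
    return CrossoverClass(pattern, intervals)


# ---------------------------------------------------------------------------
# Interval recombination frequencies
# ---------------------------------------------------------------------------


def interval_rfs(
    classified_counts: Mapping[CrossoverClass, int],
    order: LocusOrder,
    total: int | None = None,
) -> IntervalAnalysis:
    """Per-interval recombination frequencies from crossover-class counts.

    The RF of interval *i* is the summed count of every class whose switch
    pattern is true at *i*, divided by the progeny total, x100 — this
    reproduces the classical "single + double + triple" bookkeeping
    formulas automatically.  ``total`` defaults to the sum of the class
    counts; a declared population size may be passed instead (a mismatch is
    flagged, not an error).
    """
    count_sum = sum(classified_counts.values())
    if total is None:
        total = count_sum
    if total <= 0:
        raise GeneticsDomainError("zero progeny total")
    notes: tuple[str, ...] = ()
    if total != count_sum:
        notes = (
            f"declared progeny total {total} differs from the class-count "
            f"sum {count_sum}; frequencies use the declared total",
        )
    k = len(order.intervals)
    for cls in classified_counts:
        if len(cls.switch_pattern) != k:
            raise GeneticsDomainError(
                f"class {cls.label!r} was classified under a different order"
            )
    per_interval = []
    for i, (left, right) in enumerate(order.intervals):
        rec = sum(
            c for cls, c in classified_counts.items() if cls.switch_pattern[i]
        )
        rec_classes = tuple(
            (cls.label,) for cls in classified_counts if cls.switch_pattern[i]
        )
        per_interval.append(
            RecombinationEstimate(
                (left, right), rec / total * 100.0, "testcross", rec_classes, total
            )
        )
    end_sum = sum(e.r_percent for e in per_interval)
    # direct terminal-pair switch frequency: odd number of switches overall
    direct = sum(
        c
        for cls, c in classified_counts.items()
        if sum(cls.switch_pattern) % 2 == 1
    )
    parental = sum(c for cls, c in classified_counts.items() if cls.is_parental)
    return IntervalAnalysis(
        order,
        tuple(per_interval),
        end_sum,
        direct / total * 100.0,
        parental,
        total,
        count_sum,
        notes,
    )


# ---------------------------------------------------------------------------
# Locus-order search
# ---------------------------------------------------------------------------


def classify_gamete_counts(
    counts: CountTable,
    parent: PhasedGenotype,
    tester: PhasedGenotype,
    models: Mapping[str, TraitModel],
    order: LocusOrder,
) -> dict[CrossoverClass, int]:
    """Crossover-class counts for ``counts`` under one candidate order."""
    reindex = [counts.loci.index(l) for l in order.loci]
    out: dict[CrossoverClass, int] = {}
    for cls, n in zip(counts.classes, counts.counts):
        gamete = infer_gamete(cls, counts.loci, tester, models)
        ordered_gamete = tuple(gamete[i] for i in reindex)
        xo = classify_crossovers(ordered_gamete, parent.restrict(order.loci), order)
        out[xo] = out.get(xo, 0) + n
    return out


def search_order(
    counts: CountTable,
    parent: PhasedGenotype,
    tester: PhasedGenotype,
    models: Mapping[str, TraitModel],
    mapping_function: str = "kosambi",
) -> list[OrderScore]:
    """Rank every distinct locus order by multinomial log-likelihood.

    For each candidate order the interval recombination fractions are set
    to their MLEs (the observed switch frequencies) and the log-likelihood
    of the observed switch patterns is computed under independent intervals
    (no interference).  Ties break toward fewer multiple-crossover progeny,
    then toward the shorter map.
    """
    het_loci = [l for l in counts.loci if parent.is_heterozygous(l)]
    if len(het_loci) < 3:
        if len(het_loci) == 2:
            return [
                _score_order(
                    LocusOrder(tuple(het_loci)), counts, parent, tester, models,
                    mapping_function,
                )
            ]
        raise GeneticsDomainError(
            "order search needs at least two heterozygous loci"
        )
    scores = [
        _score_order(order, counts, parent, tester, models, mapping_function)
        for order in LocusOrder.all_orders(het_loci)
    ]
    scores.sort(
        key=lambda s: (-s.log_likelihood, s.n_multi_crossover, s.map_length_cm)
    )
    return scores


def _score_order(
    order: LocusOrder,
    counts: CountTable,
    parent: PhasedGenotype,
    tester: PhasedGenotype,
    models: Mapping[str, TraitModel],
    mapping_function: str,
) -> OrderScore:
    classified = classify_gamete_counts(counts, parent, tester, models, order)
    total = sum(classified.values())
    k = len(order.intervals)
    switch_counts = [0] * k
    for cls, n in classified.items():
        for i, s in enumerate(cls.switch_pattern):
            if s:
                switch_counts[i] += n
    rs = [c / total for c in switch_counts]
    loglik = 0.0
    for cls, n in classified.items():
        if n == 0:
            continue
        p = 1.0
        for s, r in zip(cls.switch_pattern, rs):
            p *= r if s else 1.0 - r
        loglik += n * math.log(p)  # p > 0: every observed switch has r > 0
    n_multi = sum(n for cls, n in classified.items() if cls.n_switches >= 2)
    length = sum(
        map_distance(min(r, 0.5 - 1e-12), mapping_function).cm for r in rs
    )
    return OrderScore(order, loglik, tuple(rs), n_multi, length)


# ---------------------------------------------------------------------------
# Mapping functions and map assembly
# ---------------------------------------------------------------------------


def map_distance(r: float, function: str = "kosambi") -> MapDistance:
    """Map distance (cM) from a recombination fraction.

    Kosambi: m = 25 ln[(1+2r)/(1-2r)].  Haldane: m = -50 ln(1-2r).
    Both diverge as r -> 0.5 (unlinked loci have no finite distance).
    """
    if not 0.0 <= r < 0.5:
        raise GeneticsDomainError(
            f"recombination fraction {r} outside [0, 0.5): distance undefined"
        )
    if function == "kosambi":
        cm = 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    elif function == "haldane":
        cm = -50.0 * math.log(1.0 - 2.0 * r)
    else:
        raise GeneticsDomainError(f"unknown mapping function {function!r}")
    return MapDistance(cm, function)


def inverse_map_distance(cm: float, function: str = "kosambi") -> float:
    """Recombination fraction from a map distance (inverse of :func:`map_distance`)."""
    if cm < 0:
        raise GeneticsDomainError(f"negative map distance {cm}")
    if function == "kosambi":
        return 0.5 * math.tanh(cm / 50.0)
    if function == "haldane":
        return 0.5 * (1.0 - math.exp(-cm / 50.0))
    raise GeneticsDomainError(f"unknown mapping function {function!r}")


def build_map(
    interval_r: Sequence[float],
    order: LocusOrder,
    function: str = "kosambi",
) -> list[tuple[str, float]]:
    """Cumulative locus positions (cM) from per-interval recombination fractions."""
    if len(interval_r) != len(order.intervals):
        raise GeneticsDomainError(
            f"order {order} has {len(order.intervals)} intervals, "
            f"got {len(interval_r)} estimates"
        )
    positions = [(order.loci[0], 0.0)]
    pos = 0.0
    for locus, r in zip(order.loci[1:], interval_r):
        pos += map_distance(r, function).cm
        positions.append((locus, pos))
    return positions
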