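"""Goodness-of-fit tests against Mendelian ratios and parental genotype inference.

Pearson chi-square statistics are computed without continuity correction,
which is what reproduces the published values for this kind of count data;
p-values come from the upper tail of the chi-square distribution.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

from .genetic_model import (
    ConfigurationError,
    CountTable,
    CrossSpec,
    GeneticsDomainError,
    PhasedGenotype,
    TraitModel,
    expected_progeny_distribution,
    phenotype_of,
)

__all__ = [
    "ChiSquareResult",
    "GenotypeHypothesis",
    "chi_square_gof",
    "contingency_chi_square",
    "infer_parent_genotypes",
    "reciprocal_consistency",
    "SMALL_EXPECTED_COUNT",
]

#: Expected counts below this are flagged (never merged): the classical
#: rule of thumb for chi-square approximation quality.
SMALL_EXPECTED_COUNT = 5.0


@dataclass(frozen=True)
class ChiSquareResult:
    """A Pearson chi-square test result."""

    statistic: float
    df: int
    p_value: float
    expected_counts: tuple[float, ...]
    warnings: tuple[str, ...] = ()

    def __str__(self) -> str:  # report convention: 3 d.p.
        return f"chi2={self.statistic:.3f} (df={self.df}, P={self.p_value:.3f})"


def chi_square_gof(
    observed: Sequence[float], expected_ratio: Sequence[float]
) -> ChiSquareResult:
    """Pearson goodness-of-fit test of counts against a Mendelian ratio.

    ``expected_ratio`` is any positive weighting (``(3, 1)``, ``(1, 1, 1, 1)``,
    ...); expected counts allocate the observed total proportionally.  The
    result is invariant to scaling the weights by a positive constant.
    """
    obs = np.asarray(observed, dtype=float)
    weights = np.asarray(expected_ratio, dtype=float)
    if obs.shape != weights.shape or obs.ndim != 1:
        raise GeneticsDomainError("observed and expected_ratio must match in length")
    if len(obs) < 2:
        raise GeneticsDomainError("goodness-of-fit needs at least two classes")
    if np.any(weights <= 0):
        raise GeneticsDomainError(
            "zero or negative expected weight: merge the degenerate class "
            "into a neighbour before testing"
        )
    total = obs.sum()
    if total <= 0:
        raise GeneticsDomainError("total observed count is zero")
    expected = weights / weights.sum() * total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p_value = float(stats.chi2.sf(statistic, df))
    notes = []
    if np.any(expected < SMALL_EXPECTED_COUNT):
        small = [f"{e:.2f}" for e in expected if e < SMALL_EXPECTED_COUNT]
        notes.append(
            f"expected count(s) {', '.join(small)} below "
            f"{SMALL_EXPECTED_COUNT:g}; chi-square approximation may be poor"
        )
    return ChiSquareResult(statistic, df, p_value, tuple(expected), tuple(notes))


def contingency_chi_square(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson independence test on a two-way count table.

    Expected cells are products of marginals over the grand total;
    df = (rows-1)(cols-1).  No continuity correction.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise GeneticsDomainError("contingency table must be at least 2x2")
    if np.any(arr.sum(axis=0) <= 0) or np.any(arr.sum(axis=1) <= 0):
        raise GeneticsDomainError(
            "a marginal total is zero: drop the empty row/column"
        )
    statistic, p_value, df, expected = stats.chi2_contingency(arr, correction=False)
    notes = ()
    if np.any(expected < SMALL_EXPECTED_COUNT):
        notes = (
            f"expected cell(s) below {SMALL_EXPECTED_COUNT:g}; "
            "chi-square approximation may be poor",
        )
    return ChiSquareResult(
        float(statistic), int(df), float(p_value), tuple(expected.ravel()), notes
    )


# ---------------------------------------------------------------------------
# Parental genotype inference from single-locus segregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeHypothesis:
    """One candidate parental genotype pair with its segregation fit.

    ``expected_ratio`` is the implied Mendelian ratio over ``class_labels``
    (small integers, e.g. ``(3, 1)``); ``fit`` is ``None`` for degenerate
    ratios (a single possible class) where no test statistic exists.
    """

    female_genotype: tuple[str, str]
    male_genotype: tuple[str, str]
    class_labels: tuple[str, ...]
    expected_ratio: tuple[int, ...]
    fit: ChiSquareResult | None
    verdict: str  # "accepted" | "rejected"

    @property
    def p_value(self) -> float:
        return 1.0 if self.fit is None else self.fit.p_value

    def describe(self) -> str:
        ratio = ":".join(str(x) for x in self.expected_ratio)
        geno = (
            "".join(self.female_genotype) + " x " + "".join(self.male_genotype)
        )
        tail = "perfect/degenerate fit" if self.fit is None else str(self.fit)
        return f"{geno} -> {ratio} ({tail}; {self.verdict})"


def _compatible_genotypes(label: str, model: TraitModel) -> list[tuple[str, str]]:
    out = []
    for geno in itertools.combinations_with_replacement(model.alleles, 2):
        if phenotype_of(geno, model) == label:
            out.append(geno)
    return out


def _ratio_weights(probs: Sequence[float]) -> tuple[int, ...]:
    fracs = [Fraction(p).limit_denominator(64) for p in probs]
    denom = math.lcm(*(f.denominator for f in fracs)) if fracs else 1
    ints = [int(f * denom) for f in fracs]
    g = math.gcd(*ints) if any(ints) else 1
    return tuple(i // g for i in ints)


def infer_parent_genotypes(
    observed: CountTable,
    parent_phenotypes: tuple[str, str],
    model: TraitModel,
    alpha: float = 0.05,
) -> list[GenotypeHypothesis]:
    """Rank single-locus parental-genotype hypotheses against observed counts.

    Enumerates every genotype pair compatible with the parents' phenotypes,
    derives each pair's implied progeny ratio from the forward model, and
    tests it by :func:`chi_square_gof`.  Hypotheses whose implied ratio
    assigns probability zero to an observed non-zero class are rejected
    outright.  An empty list means no single-locus model fits the parent
    phenotypes at all.
    """
    if len(observed.loci) != 1:
        raise GeneticsDomainError("genotype inference needs single-locus counts")
    female_opts = _compatible_genotypes(parent_phenotypes[0], model)
    male_opts = _compatible_genotypes(parent_phenotypes[1], model)
    hypotheses: list[GenotypeHypothesis] = []
    for fg in female_opts:
        for mg in male_opts:
            cross = CrossSpec(
                observed.cross_id,
                PhasedGenotype((model.locus,), (fg[0],), (fg[1],)),
                PhasedGenotype((model.locus,), (mg[0],), (mg[1],)),
                (model,),
            )
            dist = expected_progeny_distribution(cross)
            prob_by_label = {cls[0]: p for cls, p in zip(dist.classes, dist.probabilities)}
            # align observed classes with every label the hypothesis allows
            labels = list(dict.fromkeys(
                [c[0] for c in observed.classes]
                + [l for l in prob_by_label if prob_by_label[l] > 0]
            ))
            counts = [observed.count_of((l,)) for l in labels]
            probs = [prob_by_label.get(l, 0.0) for l in labels]
            impossible = any(c > 0 and p == 0.0 for c, p in zip(counts, probs))
            positive = [(l, c, p) for l, c, p in zip(labels, counts, probs) if p > 0]
            fit: ChiSquareResult | None = None
            if impossible:
                verdict = "rejected"
            elif len(positive) >= 2:
                fit = chi_square_gof(
                    [c for _, c, _ in positive], [p for _, _, p in positive]
                )
                verdict = "accepted" if fit.p_value >= alpha else "rejected"
            else:
                verdict = "accepted"  # degenerate 0:1-style ratio, consistent
            hypotheses.append(
                GenotypeHypothesis(
                    fg,
                    mg,
                    tuple(labels),
                    _ratio_weights(probs),
                    fit,
                    verdict,
                )
            )
    hypotheses.sort(key=lambda h: (h.verdict == "rejected", -h.p_value))
    return hypotheses


def reciprocal_consistency(
    cross_a: CountTable, cross_b: CountTable
) -> ChiSquareResult:
    """Contingency test of class proportions between two reciprocal crosses.

    A high p-value is consistent with no maternal (cytoplasmic) effect on
    the trait: the segregation pattern does not depend on cross direction.
    """
    if set(cross_a.classes) != set(cross_b.classes):
        raise GeneticsDomainError(
            f"reciprocal crosses report different classes: "
            f"{sorted(cross_a.classes)} vs {sorted(cross_b.classes)}"
        )
    classes = list(cross_a.classes)
    table = [
        [cross_a.count_of(c) for c in classes],
        [cross_b.count_of(c) for c in classes],
    ]
    return contingency_chi_square(table)
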