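"""Seedable progeny simulator and exact enumeration oracle.

``oracle_probabilities`` enumerates meiosis directly — every combination of
homolog-origin vectors for both parents — without going through the gamete
distribution code in :mod:`linkagekit.genetic_model`, so the two routes
check each other.  ``simulate_progeny`` draws one multinomial sample of the
class counts; identical specs (including seed) give identical tables.

Sub-seed splitting rule: ``replicate_study`` feeds the study seed to
``numpy.random.SeedSequence`` and spawns one child per simulation spec, in
list order.  This is stable across runs and versions of this package.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genetic_model import (
    ClassDistribution,
    ConfigurationError,
    CountTable,
    CrossSpec,
    GeneticsDomainError,
    PhasedGenotype,
    canonical_class_order,
    phenotype_of,
)

__all__ = [
    "SimulationSpec",
    "oracle_probabilities",
    "simulate_progeny",
    "replicate_study",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate one progeny population, reproducibly.

    ``female_rs`` / ``male_rs`` are per-interval recombination fractions
    along each parent's locus order (ignored for homozygous parents, whose
    gametes are constant).  ``misclassification_rate`` is the probability
    that the scored phenotype at a locus is replaced by a different
    (equally likely) observable label at that locus; default 0 (phenotyping
    assumed error-free).
    """

    cross: CrossSpec
    n_progeny: int
    seed: int
    female_rs: tuple[float, ...] = ()
    male_rs: tuple[float, ...] = ()
    interference_c: float = 1.0
    misclassification_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_progeny <= 0:
            raise GeneticsDomainError("n_progeny must be positive")
        if not 0.0 <= self.misclassification_rate < 0.5:
            raise GeneticsDomainError(
                f"misclassification_rate {self.misclassification_rate} "
                "outside [0, 0.5)"
            )


def _gametes_by_meiosis(
    parent: PhasedGenotype,
    interval_rs: Sequence[float],
    interference_c: float,
) -> dict[tuple[str, ...], float]:
    """Gamete distribution by explicit origin-vector enumeration.

    Deliberately independent of ``genetic_model.enumerate_gametes``: loops
    over all 2^k homolog-origin vectors and accumulates their probabilities
    term by term.
    """
    k = len(parent.loci)
    rs = tuple(interval_rs) if k > 1 else ()
    if k > 1 and len(rs) != k - 1:
        raise GeneticsDomainError(
            f"expected {k - 1} interval fractions for {k} loci, got {len(rs)}"
        )
    for r in rs:
        if not 0.0 <= r <= 0.5:
            raise GeneticsDomainError(f"recombination fraction {r} outside [0, 0.5]")
    if not 0.0 <= interference_c <= 1.0:
        raise GeneticsDomainError(
            f"coefficient of coincidence {interference_c} outside [0, 1]"
        )
    if interference_c != 1.0 and k != 3:
        raise GeneticsDomainError(
            "interference (c != 1) supported only for three-locus parents"
        )
    haps = (parent.haplotype_a, parent.haplotype_b)
    out: dict[tuple[str, ...], float] = {}
    for origins in itertools.product((0, 1), repeat=k):
        switches = [origins[i] != origins[i + 1] for i in range(k - 1)]
        if interference_c != 1.0:
            r1, r2 = rs
            dbl = interference_c * r1 * r2
            table = {
                (True, True): dbl,
                (True, False): r1 - dbl,
                (False, True): r2 - dbl,
                (False, False): 1.0 - r1 - r2 + dbl,
            }
            prob = 0.5 * table[(switches[0], switches[1])]
        else:
            prob = 0.5
            for sw, r in zip(switches, rs):
                prob *= r if sw else 1.0 - r
        if prob == 0.0:
            continue
        gamete = tuple(haps[o][i] for i, o in enumerate(origins))
        out[gamete] = out.get(gamete, 0.0) + prob
    return out


def oracle_probabilities(spec: SimulationSpec) -> ClassDistribution:
    """Exact progeny phenotype-class probabilities by full enumeration.

    Independent of the sample size and seed; serves as the ground truth
    both for the simulator and for cross-checking the analytical forward
    model.
    """
    cross = spec.cross
    g_f = _gametes_by_meiosis(cross.female, spec.female_rs, spec.interference_c)
    g_m = _gametes_by_meiosis(cross.male, spec.male_rs, spec.interference_c)
    models = [cross.model_for(l) for l in cross.loci]
    acc: dict[tuple[str, ...], float] = {}
    for hap_f, p_f in g_f.items():
        for hap_m, p_m in g_m.items():
            labels = tuple(
                phenotype_of((a, b), m) for a, b, m in zip(hap_f, hap_m, models)
            )
            acc[labels] = acc.get(labels, 0.0) + p_f * p_m
    if spec.misclassification_rate > 0.0:
        acc = _apply_misclassification(acc, models, spec.misclassification_rate)
    ordered = canonical_class_order(acc, models)
    return ClassDistribution(tuple(ordered), tuple(acc[c] for c in ordered))


def _apply_misclassification(
    class_probs: Mapping[tuple[str, ...], float],
    models: Sequence,
    rate: float,
) -> dict[tuple[str, ...], float]:
    """Symmetric per-locus scoring noise over the observable labels.

    With probability ``rate`` the recorded label at a locus is replaced by
    one of the *other* labels observable at that locus in this cross,
    uniformly; loci are perturbed independently.
    """
    observable = [
        sorted({cls[i] for cls in class_probs}) for i in range(len(models))
    ]
    out: dict[tuple[str, ...], float] = {}
    for cls, p in class_probs.items():
        per_locus: list[list[tuple[str, float]]] = []
        for i, label in enumerate(cls):
            others = [l for l in observable[i] if l != label]
            if not others:
                per_locus.append([(label, 1.0)])
                continue
            opts = [(label, 1.0 - rate)]
            opts += [(o, rate / len(others)) for o in others]
            per_locus.append(opts)
        for combo in itertools.product(*per_locus):
            labels = tuple(l for l, _ in combo)
            w = p
            for _, q in combo:
                w *= q
            out[labels] = out.get(labels, 0.0) + w
    return out


def simulate_progeny(spec: SimulationSpec) -> CountTable:
    """One multinomial draw of ``spec.n_progeny`` progeny.

    Deterministic given the spec (the seed is part of it); emits the same
    :class:`CountTable` shape the readers and analysis stages consume,
    including zero-count classes so the class list is reproducible.
    """
    dist = oracle_probabilities(spec)
    rng = np.random.default_rng(spec.seed)
    draws = rng.multinomial(spec.n_progeny, np.asarray(dist.probabilities))
    return CountTable(
        spec.cross.cross_id,
        spec.cross.loci,
        dist.classes,
        tuple(int(d) for d in draws),
    )


def replicate_study(
    templates: Sequence[SimulationSpec], seed: int
) -> dict[str, CountTable]:
    """Simulate a whole study: one count table per template spec.

    Each template's own seed is replaced by a child of ``seed`` via
    ``numpy.random.SeedSequence.spawn`` (one child per template, in order),
    so the bundle is reproducible from the single study seed.
    """
    if not templates:
        raise GeneticsDomainError("no simulation templates supplied")
    children = np.random.SeedSequence(seed).spawn(len(templates))
    out: dict[str, CountTable] = {}
    for template, child in zip(templates, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        table = simulate_progeny(replace(template, seed=sub_seed))
        if table.cross_id in out:
            raise ConfigurationError(
                f"duplicate cross_id {table.cross_id!r} in study templates"
            )
        out[table.cross_id] = table
    return out
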