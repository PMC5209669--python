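"""Two-locus joint segregation: independence, linkage phase, recombination.

The estimators implemented here are the two classical count-ratio
estimators used with phenotype-only progeny data, plus a maximum-likelihood
alternative:

``testcross``
    One parent heterozygous at both loci, the other homozygous at both
    (pseudo-BC1).  Every progeny class reveals one gamete of the informative
    parent, so r = (recombinant progeny) / n.

``f2_double_recessive``
    Both parents heterozygous at one shared locus, one of them also
    heterozygous at the second (the 3:3:1:1 design).  Only the class that
    requires a recombinant gamete (probability zero at r = 0) is
    unambiguously recombinant; the estimator reported by this package's
    reference tables multiplies that class frequency by 2.  Under the
    forward model that class has frequency r/4, so the frequency-matching
    factor would be 4 (``f2_unbiased``) — both are available, as is
    ``max_likelihood``, which needs no factor at all.

Recombinant classes are never hand-listed: a class is recombinant for a
given phase exactly when its probability under the forward model vanishes
at r = 0 and grows with r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .genetic_model import (
    ClassDistribution,
    CountTable,
    CrossSpec,
    GeneticsDomainError,
    PhasedGenotype,
    canonical_class_order,
    expected_progeny_distribution,
)
from .segregation import ChiSquareResult, chi_square_gof

__all__ = [
    "PhaseAssignment",
    "RecombinationEstimate",
    "AggregateEstimate",
    "joint_independence_test",
    "infer_phase",
    "estimate_rf",
    "aggregate_rf",
]

_EPS = 1e-9
_PROBE_R = 0.02  # small r used to detect which classes grow with recombination


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseAssignment:
    """Inferred linkage phase of the doubly heterozygous parent.

    ``haplotypes`` is the inferred phased arrangement over ``loci`` (or
    ``None`` when the excess pattern is ambiguous / counts sit at
    independence).  ``evidence`` lists the jointly over-represented
    phenotype classes supporting the call.
    """

    parent_role: str  # "female" | "male"
    loci: tuple[str, str]
    haplotypes: tuple[tuple[str, str], tuple[str, str]] | None
    determined: bool
    evidence: tuple[tuple[str, ...], ...] = ()

    def pairing(self, allele_first: str, allele_second: str) -> str:
        """``"coupling"`` if the two alleles share a haplotype, else ``"repulsion"``."""
        if not self.determined or self.haplotypes is None:
            raise GeneticsDomainError("phase undetermined: no pairing to report")
        for hap in self.haplotypes:
            if hap[0] == allele_first and hap[1] == allele_second:
                return "coupling"
        a_present = any(h[0] == allele_first for h in self.haplotypes)
        b_present = any(h[1] == allele_second for h in self.haplotypes)
        if not (a_present and b_present):
            raise GeneticsDomainError(
                f"alleles ({allele_first!r}, {allele_second!r}) not carried by "
                f"the phased parent {self.haplotypes}"
            )
        return "repulsion"


@dataclass(frozen=True)
class RecombinationEstimate:
    """A recombination-fraction estimate between two loci.

    ``r_percent`` is on the paper-table scale (0-100); the raw fraction is
    available as :attr:`r_fraction`.
    """

    loci: tuple[str, str]
    r_percent: float
    estimator: str
    recombinant_classes: tuple[tuple[str, ...], ...]
    n: int
    warnings: tuple[str, ...] = ()

    @property
    def r_fraction(self) -> float:
        return self.r_percent / 100.0


@dataclass(frozen=True)
class AggregateEstimate:
    """Unweighted mean +/- sample SD over per-cross estimates of one locus pair."""

    loci: tuple[str, str]
    mean_percent: float
    sd_percent: float | None  # None when only one estimate (SD undefined)
    k: int

    def __str__(self) -> str:
        sd = "" if self.sd_percent is None else f" (+/-{self.sd_percent:.2f})"
        return f"{self.mean_percent:.2f}{sd} over {self.k} cross(es)"


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _restrict_to_counts(cross: CrossSpec, counts: CountTable) -> CrossSpec:
    if cross.loci != counts.loci:
        cross = cross.restrict(counts.loci)
    if len(cross.loci) != 2:
        raise GeneticsDomainError(
            f"pairwise analysis needs exactly two loci, got {cross.loci}"
        )
    return cross


def _het_both(parent: PhasedGenotype) -> bool:
    return all(parent.is_heterozygous(l) for l in parent.loci)


def _informative_parent(cross: CrossSpec) -> str:
    """Role of the (single) parent heterozygous at both loci."""
    f, m = _het_both(cross.female), _het_both(cross.male)
    if f and m:
        raise GeneticsDomainError(
            f"cross {cross.cross_id!r}: both parents doubly heterozygous; "
            "phase/estimator selection is ambiguous for this design"
        )
    if not (f or m):
        raise GeneticsDomainError(
            f"cross {cross.cross_id!r}: no parent is heterozygous at both loci"
        )
    return "female" if f else "male"


def _with_parent_phase(
    cross: CrossSpec, role: str, haplotypes: tuple[tuple[str, str], tuple[str, str]]
) -> CrossSpec:
    parent = PhasedGenotype(cross.loci, haplotypes[0], haplotypes[1])
    if role == "female":
        return CrossSpec(cross.cross_id, parent, cross.male, cross.trait_models, cross.design_tag)
    return CrossSpec(cross.cross_id, cross.female, parent, cross.trait_models, cross.design_tag)


def _distribution_at(cross: CrossSpec, role: str, r: float) -> ClassDistribution:
    """Class distribution with interval fraction ``r`` in the informative parent."""
    rs = (r,)
    half = (0.5,)
    if role == "female":
        return expected_progeny_distribution(cross, rs, half)
    return expected_progeny_distribution(cross, half, rs)


def _aligned_counts(
    counts: CountTable, dist: ClassDistribution
) -> tuple[list[tuple[str, ...]], list[int], list[float]]:
    """Union of observed and model classes; zero counts are retained."""
    classes = list(dist.classes)
    for cls in counts.classes:
        if cls not in classes:
            classes.append(cls)
    obs = [counts.count_of(c) for c in classes]
    probs = [dist.prob_of(c) for c in classes]
    return classes, obs, probs


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def joint_independence_test(counts: CountTable, cross: CrossSpec) -> ChiSquareResult:
    """Goodness-of-fit of the joint classes against the r = 0.5 expectation.

    The expected ratio is derived from the forward model with free
    recombination (e.g. 1:1:1:1 for a pseudo-BC1, 3:3:1:1 for the paper's
    intercross design); classes expected but unobserved are retained at
    count zero.
    """
    cross = _restrict_to_counts(cross, counts)
    dist = expected_progeny_distribution(cross)  # all r = 0.5
    classes, obs, probs = _aligned_counts(counts, dist)
    for cls, c, p in zip(classes, obs, probs):
        if c > 0 and p == 0.0:
            raise GeneticsDomainError(
                f"cross {counts.cross_id!r}: observed class {cls} is impossible "
                "under the declared parental genotypes"
            )
    keep = [i for i, p in enumerate(probs) if p > 0]
    return chi_square_gof([obs[i] for i in keep], [probs[i] for i in keep])


def infer_phase(
    counts: CountTable, cross: CrossSpec, alpha: float = 0.05
) -> PhaseAssignment:
    """Infer the linkage phase of the doubly heterozygous parent.

    The candidate phase whose parental (low-r-favoured) classes are jointly
    over-represented relative to the independence expectation is returned.
    If independence is not rejected at ``alpha``, or neither/both candidate
    phases are supported by the excess pattern, the result is explicitly
    phase-undetermined.
    """
    cross = _restrict_to_counts(cross, counts)
    if not (_het_both(cross.female) or _het_both(cross.male)):
        # no parent carries joint phase information (e.g. each parent
        # heterozygous at a different locus): nothing to determine
        return PhaseAssignment("none", cross.loci, None, determined=False)
    role = _informative_parent(cross)
    parent = cross.female if role == "female" else cross.male
    (a1, a2), (b1, b2) = parent.haplotype_a, parent.haplotype_b
    variants = (
        ((a1, a2), (b1, b2)),  # as declared
        ((a1, b2), (b1, a2)),  # alternative pairing
    )

    indep = joint_independence_test(counts, cross)
    if indep.p_value >= alpha:
        return PhaseAssignment(role, cross.loci, None, determined=False)

    dist_half = expected_progeny_distribution(cross)
    classes, obs, probs = _aligned_counts(counts, dist_half)
    total = sum(obs)
    expected = [p * total for p in probs]

    supported: list[tuple[tuple[tuple[str, str], tuple[str, str]], tuple]] = []
    for haps in variants:
        variant_cross = _with_parent_phase(cross, role, haps)
        dist_low = _distribution_at(variant_cross, role, _PROBE_R)
        favoured = [
            cls
            for cls, p_half in zip(classes, probs)
            if dist_low.prob_of(cls) > p_half + _EPS
        ]
        if favoured and all(
            obs[classes.index(cls)] > expected[classes.index(cls)] for cls in favoured
        ):
            supported.append((haps, tuple(favoured)))

    if len(supported) != 1:
        return PhaseAssignment(role, cross.loci, None, determined=False)
    haps, evidence = supported[0]
    return PhaseAssignment(role, cross.loci, haps, determined=True, evidence=evidence)


def _recombinant_classes(
    cross: CrossSpec, role: str
) -> tuple[tuple[str, ...], ...]:
    """Classes whose probability is zero at r = 0 and increases with r."""
    dist0 = _distribution_at(cross, role, 0.0)
    dist_probe = _distribution_at(cross, role, _PROBE_R)
    rec = [
        cls
        for cls in dist_probe.classes
        if dist0.prob_of(cls) < _EPS and dist_probe.prob_of(cls) > _EPS
    ]
    models = [cross.model_for(l) for l in cross.loci]
    return tuple(canonical_class_order(rec, models))


def estimate_rf(
    counts: CountTable,
    cross: CrossSpec,
    phase: PhaseAssignment | None = None,
    estimator: str | None = None,
) -> RecombinationEstimate:
    """Estimate the recombination fraction between the two loci of ``counts``.

    The estimator is selected from the cross design unless overridden:
    ``testcross`` when one parent is doubly heterozygous and the other
    doubly homozygous, ``f2_double_recessive`` when the other parent shares
    one heterozygous locus.  Overrides: ``"f2_unbiased"`` (frequency-matching
    factor 4) and ``"max_likelihood"`` (bounded multinomial ML on [0, 0.5]).
    """
    cross = _restrict_to_counts(cross, counts)
    role = _informative_parent(cross)
    if phase is not None:
        if not phase.determined or phase.haplotypes is None:
            raise GeneticsDomainError(
                f"cross {counts.cross_id!r}: phase undetermined; cannot estimate r"
            )
        if tuple(phase.loci) != cross.loci:
            raise GeneticsDomainError(
                f"phase is over loci {phase.loci}, counts over {cross.loci}"
            )
        cross = _with_parent_phase(cross, phase.parent_role, phase.haplotypes)

    other = cross.male if role == "female" else cross.female
    other_het = sum(other.is_heterozygous(l) for l in cross.loci)
    if other_het == 0:
        design = "testcross"
    elif other_het == 1:
        design = "f2_double_recessive"
    else:  # pragma: no cover - _informative_parent already rejects this
        design = "unsupported"
    if estimator is None:
        if design == "unsupported":
            raise GeneticsDomainError(
                f"cross {counts.cross_id!r}: design matches neither the "
                "testcross nor the double-recessive template; pass an "
                "explicit estimator"
            )
        estimator = design

    rec_classes = _recombinant_classes(cross, role)
    n = counts.total
    if n == 0:
        raise GeneticsDomainError(f"cross {counts.cross_id!r}: no progeny")
    rec_count = sum(counts.count_of(c) for c in rec_classes)

    if estimator == "testcross":
        r_percent = rec_count / n * 100.0
    elif estimator == "f2_double_recessive":
        r_percent = rec_count / n * 2.0 * 100.0
    elif estimator == "f2_unbiased":
        r_percent = rec_count / n * 4.0 * 100.0
    elif estimator == "max_likelihood":
        r_percent = _max_likelihood_r(counts, cross, role) * 100.0
    else:
        raise GeneticsDomainError(f"unknown estimator {estimator!r}")

    notes = []
    if r_percent > 50.0:
        notes.append(
            f"estimate {r_percent:.2f}% exceeds 50%: inconsistent with "
            "linkage; loci are likely unlinked or the phase is wrong"
        )
    return RecombinationEstimate(
        cross.loci, r_percent, estimator, rec_classes, n, tuple(notes)
    )


def _max_likelihood_r(counts: CountTable, cross: CrossSpec, role: str) -> float:
    classes = list(counts.classes)
    obs = np.array([counts.count_of(c) for c in classes], dtype=float)

    def nll(r: float) -> float:
        dist = _distribution_at(cross, role, r)
        probs = np.array([dist.prob_of(c) for c in classes])
        if np.any((probs <= 0) & (obs > 0)):
            return np.inf
        with np.errstate(divide="ignore"):
            logp = np.where(obs > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
        return -float(np.sum(obs * logp))

    res = optimize.minimize_scalar(
        nll, bounds=(_EPS, 0.5 - _EPS), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def aggregate_rf(
    estimates: Sequence[RecombinationEstimate], ndigits: int = 2
) -> AggregateEstimate:
    """Unweighted mean and sample SD (k-1 denominator) of per-cross estimates.

    Estimates are taken at report precision (``ndigits`` decimal places,
    matching the per-cross values as tabulated) before averaging, which is
    the convention of the source tables.  SD is undefined (``None``) for a
    single estimate.
    """
    if not estimates:
        raise GeneticsDomainError("no estimates to aggregate")
    pairs = {frozenset(e.loci) for e in estimates}
    if len(pairs) != 1:
        raise GeneticsDomainError(
            f"cannot aggregate estimates over different locus pairs: {pairs}"
        )
    values = [round(e.r_percent, ndigits) for e in estimates]
    k = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if k > 1 else None
    return AggregateEstimate(estimates[0].loci, mean, sd, k)
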