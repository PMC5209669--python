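"""Core domain types for classical (phenotype-based) linkage genetics.

This module models single-locus traits with a strict dominance series,
phased multi-locus parental genotypes, and the forward model from meiosis
(gamete formation with per-interval recombination) to the phenotype-class
distribution expected in progeny of a cross.

Conventions
-----------
* A *genotype* at one locus is an unordered pair of allele symbols; phase
  (which allele sits on which homolog) lives only in :class:`PhasedGenotype`.
* Allele symbols within a :class:`TraitModel` are listed most-dominant
  first; a heterozygote shows the phenotype of its most dominant allele
  unless the locus is codominant, in which case each genotype has its own
  label (e.g. leaf shape ``FF`` fancy / ``Ff`` lance / ``ff`` strap).
* Recombination fractions ``r`` are per adjacent-locus interval, in
  ``[0, 0.5]``; ``r = 0.5`` means free recombination (unlinked).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "GeneticsDomainError",
    "TraitModel",
    "PhasedGenotype",
    "CrossSpec",
    "PhenotypeClass",
    "ClassDistribution",
    "CountTable",
    "phenotype_of",
    "enumerate_gametes",
    "expected_progeny_distribution",
]

_PROB_TOL = 1e-12


class ConfigurationError(ValueError):
    """A trait model, genotype, or cross declaration is inconsistent."""


class GeneticsDomainError(ValueError):
    """An analysis-time argument is outside its mathematical domain."""


# ---------------------------------------------------------------------------
# Trait models and phenotype resolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitModel:
    """One locus with an ordered dominance series of alleles.

    Parameters
    ----------
    locus : str
        Locus name (e.g. ``"LEM"``, ``"V"``).
    alleles : tuple of str
        Allele symbols, most dominant first; the dominance series is a
        strict total order (e.g. ``V^r > V^w > V^g``).
    phenotypes : mapping
        For a dominant-series locus, a map *allele -> phenotype label*
        (the label a genotype shows is that of its most dominant allele).
        For a codominant locus, a map *"A/B" genotype key -> label* where
        the key joins the two alleles, dominance-rank-sorted, with ``"/"``.
    codominant : bool
        Whether every genotype is phenotypically distinguishable.
    """

    locus: str
    alleles: tuple[str, ...]
    phenotypes: Mapping[str, str]
    codominant: bool = False

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ConfigurationError(
                f"locus {self.locus!r}: duplicate allele symbols in {self.alleles}"
            )
        if not self.alleles:
            raise ConfigurationError(f"locus {self.locus!r}: no alleles declared")
        if self.codominant:
            for geno in itertools.combinations_with_replacement(self.alleles, 2):
                key = self.genotype_key(geno)
                if key not in self.phenotypes:
                    raise ConfigurationError(
                        f"locus {self.locus!r}: codominant model lacks a label "
                        f"for genotype {key!r}"
                    )
            # heterozygote labels must differ from both homozygote labels
            for a, b in itertools.combinations(self.alleles, 2):
                het = self.phenotypes[self.genotype_key((a, b))]
                if het in (
                    self.phenotypes[self.genotype_key((a, a))],
                    self.phenotypes[self.genotype_key((b, b))],
                ):
                    raise ConfigurationError(
                        f"locus {self.locus!r}: codominant heterozygote "
                        f"{a}/{b} shares its label {het!r} with a homozygote"
                    )
        else:
            missing = [a for a in self.alleles if a not in self.phenotypes]
            if missing:
                raise ConfigurationError(
                    f"locus {self.locus!r}: no phenotype label for allele(s) {missing}"
                )

    def rank(self, allele: str) -> int:
        """Dominance rank of ``allele`` (0 = most dominant)."""
        try:
            return self.alleles.index(allele)
        except ValueError:
            raise ConfigurationError(
                f"unknown allele {allele!r} at locus {self.locus!r}"
            ) from None

    def genotype_key(self, genotype: Iterable[str]) -> str:
        """Canonical ``"A/B"`` key for an unordered genotype."""
        a, b = sorted(genotype, key=self.rank)
        return f"{a}/{b}"

    def label_order(self) -> tuple[str, ...]:
        """Phenotype labels in canonical (dominance-derived) display order."""
        seen: dict[str, None] = {}
        for geno in itertools.combinations_with_replacement(self.alleles, 2):
            seen.setdefault(phenotype_of(geno, self), None)
        return tuple(seen)


def phenotype_of(genotype: Iterable[str], model: TraitModel) -> str:
    """Phenotype label of an unordered allele pair under ``model``.

    The label is that of the most dominant allele present; for codominant
    models each genotype carries its own label.
    """
    pair = tuple(genotype)
    if len(pair) != 2:
        raise ConfigurationError(
            f"locus {model.locus!r}: a genotype is an allele pair, got {pair}"
        )
    for allele in pair:
        model.rank(allele)  # validates symbols
    if model.codominant:
        return model.phenotypes[model.genotype_key(pair)]
    top = min(pair, key=model.rank)
    return model.phenotypes[top]


# ---------------------------------------------------------------------------
# Phased genotypes and crosses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhasedGenotype:
    """Two haplotypes over an ordered list of loci.

    The classical ``A b // a B`` phase notation maps onto
    ``haplotype_a = (A, b)``, ``haplotype_b = (a, B)``. A fully homozygous
    tester has identical haplotypes.
    """

    loci: tuple[str, ...]
    haplotype_a: tuple[str, ...]
    haplotype_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.loci) == len(self.haplotype_a) == len(self.haplotype_b)):
            raise ConfigurationError(
                f"phased genotype over {self.loci}: haplotype lengths "
                f"{len(self.haplotype_a)}/{len(self.haplotype_b)} do not match"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ConfigurationError(f"duplicate locus names in {self.loci}")

    def index_of(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise ConfigurationError(f"locus {locus!r} not in {self.loci}") from None

    def alleles_at(self, locus: str) -> tuple[str, str]:
        i = self.index_of(locus)
        return (self.haplotype_a[i], self.haplotype_b[i])

    def is_heterozygous(self, locus: str) -> bool:
        a, b = self.alleles_at(locus)
        return a != b

    def swapped(self) -> "PhasedGenotype":
        """The same genotype with the two homologs relabelled."""
        return PhasedGenotype(self.loci, self.haplotype_b, self.haplotype_a)

    def restrict(self, loci: Sequence[str]) -> "PhasedGenotype":
        """Sub-genotype over ``loci`` (kept in the order given)."""
        idx = [self.index_of(l) for l in loci]
        return PhasedGenotype(
            tuple(loci),
            tuple(self.haplotype_a[i] for i in idx),
            tuple(self.haplotype_b[i] for i in idx),
        )

    def notation(self) -> str:
        """The field's ``//`` phase notation, e.g. ``"S lem//s LEM"``."""
        return " ".join(self.haplotype_a) + "//" + " ".join(self.haplotype_b)


@dataclass(frozen=True)
class CrossSpec:
    """A cross between two phased parents with the trait models they segregate."""

    cross_id: str
    female: PhasedGenotype
    male: PhasedGenotype
    trait_models: tuple[TraitModel, ...]
    design_tag: str = "mixed"  # advisory; estimator choice derives from genotypes

    _VALID_TAGS = frozenset({"self", "intercross", "testcross", "pseudo_bc1", "mixed"})

    def __post_init__(self) -> None:
        if self.female.loci != self.male.loci:
            raise ConfigurationError(
                f"cross {self.cross_id!r}: parents have different locus orders "
                f"{self.female.loci} vs {self.male.loci}"
            )
        if self.design_tag not in self._VALID_TAGS:
            raise ConfigurationError(
                f"cross {self.cross_id!r}: unknown design_tag {self.design_tag!r}"
            )
        by_locus = {m.locus: m for m in self.trait_models}
        for locus in self.female.loci:
            if locus not in by_locus:
                raise ConfigurationError(
                    f"cross {self.cross_id!r}: no trait model for locus {locus!r}"
                )
            model = by_locus[locus]
            for parent in (self.female, self.male):
                for allele in parent.alleles_at(locus):
                    model.rank(allele)

    @property
    def loci(self) -> tuple[str, ...]:
        return self.female.loci

    def model_for(self, locus: str) -> TraitModel:
        for m in self.trait_models:
            if m.locus == locus:
                return m
        raise ConfigurationError(f"no trait model for locus {locus!r}")

    def restrict(self, loci: Sequence[str]) -> "CrossSpec":
        return CrossSpec(
            self.cross_id,
            self.female.restrict(loci),
            self.male.restrict(loci),
            tuple(self.model_for(l) for l in loci),
            self.design_tag,
        )

    def segregating_loci(self) -> tuple[str, ...]:
        """Loci heterozygous in at least one parent."""
        return tuple(
            l
            for l in self.loci
            if self.female.is_heterozygous(l) or self.male.is_heterozygous(l)
        )


# ---------------------------------------------------------------------------
# Phenotype classes, distributions and observed count tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeClass:
    """One progeny phenotype class: one label per locus, in locus order."""

    labels: tuple[str, ...]
    count: int | None = None


@dataclass(frozen=True)
class ClassDistribution:
    """Phenotype classes with their probabilities (sums to one)."""

    classes: tuple[tuple[str, ...], ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.probabilities):
            raise ConfigurationError("classes and probabilities differ in length")
        if len(set(self.classes)) != len(self.classes):
            raise ConfigurationError("phenotype classes are not distinct")
        if any(p < -_PROB_TOL for p in self.probabilities):
            raise ConfigurationError("negative class probability")
        total = math.fsum(self.probabilities)
        if abs(total - 1.0) > _PROB_TOL:
            raise ConfigurationError(f"class probabilities sum to {total}, not 1")

    def prob_of(self, labels: Sequence[str]) -> float:
        key = tuple(labels)
        for cls, p in zip(self.classes, self.probabilities):
            if cls == key:
                return p
        return 0.0

    def as_dict(self) -> dict[tuple[str, ...], float]:
        return dict(zip(self.classes, self.probabilities))


@dataclass(frozen=True)
class CountTable:
    """Observed progeny counts per phenotype class for one cross."""

    cross_id: str
    loci: tuple[str, ...]
    classes: tuple[tuple[str, ...], ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.counts):
            raise ConfigurationError(
                f"cross {self.cross_id!r}: classes and counts differ in length"
            )
        if len(set(self.classes)) != len(self.classes):
            raise ConfigurationError(f"cross {self.cross_id!r}: duplicate classes")
        for cls in self.classes:
            if len(cls) != len(self.loci):
                raise ConfigurationError(
                    f"cross {self.cross_id!r}: class {cls} does not match loci "
                    f"{self.loci}"
                )
        if any(c < 0 for c in self.counts):
            raise ConfigurationError(f"cross {self.cross_id!r}: negative count")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def count_of(self, labels: Sequence[str]) -> int:
        key = tuple(labels)
        for cls, c in zip(self.classes, self.counts):
            if cls == key:
                return c
        return 0

    def as_dict(self) -> dict[tuple[str, ...], int]:
        return dict(zip(self.classes, self.counts))


def canonical_class_order(
    classes: Iterable[tuple[str, ...]], models: Sequence[TraitModel]
) -> list[tuple[str, ...]]:
    """Deterministic display order: locus by locus, dominance rank first."""
    orders = [m.label_order() for m in models]

    def key(cls: tuple[str, ...]) -> tuple[int, ...]:
        return tuple(
            order.index(lbl) if lbl in order else len(order)
            for lbl, order in zip(cls, orders)
        )

    return sorted(classes, key=key)


# ---------------------------------------------------------------------------
# Forward model: meiosis and progeny class probabilities
# ---------------------------------------------------------------------------


def _switch_pattern_probs(
    interval_rs: Sequence[float], interference_c: float
) -> dict[tuple[int, ...], float]:
    """Probability of each haplotype-origin switch pattern across intervals.

    Under no interference (``c = 1``) intervals recombine independently with
    their own ``r``.  With ``c != 1`` (supported for exactly two intervals,
    i.e. three loci) the double-crossover probability is ``c * r1 * r2`` and
    the marginals are preserved.
    """
    for r in interval_rs:
        if not 0.0 <= r <= 0.5:
            raise GeneticsDomainError(
                f"recombination fraction {r} outside [0, 0.5]"
            )
    if not 0.0 <= interference_c <= 1.0:
        raise GeneticsDomainError(
            f"coefficient of coincidence {interference_c} outside [0, 1]"
        )
    k = len(interval_rs)
    if interference_c != 1.0 and k > 2:
        raise GeneticsDomainError(
            "interference (c != 1) is supported only for two-interval "
            "(three-locus) parents"
        )
    if interference_c != 1.0 and k == 2:
        r1, r2 = interval_rs
        dbl = interference_c * r1 * r2
        return {
            (1, 1): dbl,
            (1, 0): r1 - dbl,
            (0, 1): r2 - dbl,
            (0, 0): 1.0 - r1 - r2 + dbl,
        }
    probs: dict[tuple[int, ...], float] = {}
    for pattern in itertools.product((0, 1), repeat=k):
        p = 1.0
        for s, r in zip(pattern, interval_rs):
            p *= r if s else 1.0 - r
        probs[pattern] = p
    return probs


def enumerate_gametes(
    parent: PhasedGenotype,
    interval_rs: Sequence[float] = (),
    interference_c: float = 1.0,
) -> dict[tuple[str, ...], float]:
    """Distribution over gamete haplotypes produced by ``parent``.

    ``interval_rs`` gives one recombination fraction per adjacent locus
    pair of ``parent.loci``; a gamete's probability is ``1/2`` times the
    product over intervals of ``r_i`` (if the gamete switches haplotype
    origin across that interval) or ``1 - r_i`` (if it does not).  Loci
    homozygous in the parent contribute their single allele
    deterministically, which merges origin patterns that yield the same
    haplotype.
    """
    k = len(parent.loci)
    if k > 1 and len(interval_rs) != k - 1:
        raise GeneticsDomainError(
            f"expected {k - 1} interval recombination fractions for "
            f"{k} loci, got {len(interval_rs)}"
        )
    pattern_probs = _switch_pattern_probs(tuple(interval_rs), interference_c)
    haps = (parent.haplotype_a, parent.haplotype_b)
    out: dict[tuple[str, ...], float] = {}
    for pattern, p_pattern in pattern_probs.items():
        if p_pattern == 0.0:
            continue
        for start in (0, 1):
            origin = start
            gamete = [haps[origin][0]] if k else []
            for i, s in enumerate(pattern):
                origin ^= s
                gamete.append(haps[origin][i + 1])
            key = tuple(gamete)
            out[key] = out.get(key, 0.0) + 0.5 * p_pattern
    return out


def expected_progeny_distribution(
    cross: CrossSpec,
    female_rs: Sequence[float] = (),
    male_rs: Sequence[float] = (),
    interference_c: float = 1.0,
) -> ClassDistribution:
    """Expected phenotype-class distribution in progeny of ``cross``.

    Convolves both parents' gamete distributions, maps each offspring
    genotype to its phenotype class via :func:`phenotype_of`, and
    aggregates probabilities by class.  With all ``r = 0.5`` this is the
    classical Mendelian joint ratio (e.g. 3:1, 1:1:1:1, 3:3:1:1).
    """
    k = len(cross.loci)
    female_rs = tuple(female_rs) if female_rs else (0.5,) * max(k - 1, 0)
    male_rs = tuple(male_rs) if male_rs else (0.5,) * max(k - 1, 0)
    g_f = enumerate_gametes(cross.female, female_rs, interference_c)
    g_m = enumerate_gametes(cross.male, male_rs, interference_c)
    models = [cross.model_for(l) for l in cross.loci]
    acc: dict[tuple[str, ...], float] = {}
    for hap_f, p_f in g_f.items():
        for hap_m, p_m in g_m.items():
            labels = tuple(
                phenotype_of((a, b), m) for a, b, m in zip(hap_f, hap_m, models)
            )
            acc[labels] = acc.get(labels, 0.0) + p_f * p_m
    ordered = canonical_class_order(acc, models)
    return ClassDistribution(tuple(ordered), tuple(acc[c] for c in ordered))
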