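# Methods

## Model and scope

`linkagekit` analyses two-generation crosses in which each locus is scored
only by phenotype. The genetic model is deliberately classical:

* one locus = one strict dominance series of alleles (most dominant
  first); a heterozygote shows its most dominant allele's phenotype unless
  the locus is flagged codominant, in which case each genotype carries its
  own label (leaf shape *FF*/*Ff*/*ff* → fancy/lance/strap);
* phase lives only in `PhasedGenotype` (the `A b//a B` notation of the
  breeding literature); unordered genotypes determine phenotype;
* meiosis is modelled by per-interval recombination fractions
  r ∈ [0, 0.5] along the parent's locus order. Under no interference,
  intervals recombine independently: a gamete that switches homolog origin
  across interval set *I* has probability ½ ∏_{i∈I} r_i ∏_{i∉I} (1−r_i).
  A coefficient of coincidence c ∈ [0, 1] (P(double) = c·r₁·r₂, marginals
  preserved) is supported for three-locus parents only; chi-square or
  gamma interference models are out of scope.

Excluded on purpose: quantitative traits, epistasis, cytoplasmic
inheritance (reciprocal crosses are instead *compared* by contingency
test), segregation-distortion/viability models, and maps beyond 8 loci
(the order search is exhaustive over n!/2 arrangements, 12 for four loci).

## Tests and inference

Goodness-of-fit uses the uncorrected Pearson statistic with expected
counts allocated proportionally to the hypothesized ratio and p-values
from the upper chi-square tail (the regularized incomplete gamma, via
scipy). No Yates correction anywhere: the uncorrected statistic is what
reproduces the reference tables bundled with the package. Expected counts
below 5 raise a warning but are never merged. Genotype inference
enumerates all parent genotype pairs compatible with the parent
phenotypes, derives each pair's progeny ratio from the forward model, and
ranks by p; a hypothesis giving probability 0 to an observed class is
rejected outright, and degenerate ratios (single possible class) carry no
test statistic.

Phase inference requires the two-locus independence test to reject at
alpha (default 0.05, configurable). The candidate pairing of the doubly
heterozygous parent's alleles whose low-r-favoured classes are *jointly*
over-represented relative to the independence expectation is returned;
if neither or both pairings qualify the result is explicitly
phase-undetermined, never a guess.

## Recombination estimators

Recombinant classes are derived, not hand-listed: given the (inferred)
phase, a class is recombinant exactly when its forward-model probability
is zero at r = 0 and grows with r. Three estimators:

* `testcross` — recombinant count / n. For the pseudo-testcross this is
  the binomial MLE; the test suite verifies the identity against the
  numerical ML estimator to 1e-6.
* `f2_double_recessive` — 2 × double-recessive count / n, exactly the
  published bookkeeping for the 3:3:1:1 intercross design. Note the
  forward model gives that class frequency r/4, so the frequency-matching
  factor would be 4; the ×2 convention is retained as the default because
  reproducing the reference tables takes precedence, and `f2_unbiased`
  (factor 4) and `max_likelihood` (bounded scalar search of the
  multinomial likelihood on [0, 0.5], scipy `minimize_scalar`) are exposed
  for corrected analyses. On simulated intercrosses at r = 0.10 the ML
  estimator centres on 10% while the ×2 estimator centres on 5%, as
  expected.
* `max_likelihood` — available for any supported design.

Per-pair aggregation is the unweighted mean with sample SD (k−1
denominator), computed over the per-cross estimates *at report precision*
(2 d.p.) — the convention of the reference tables, whose printed averages
and SDs are reproducible only from the rounded per-cross values. SD is
reported absent for a single cross.

## Multipoint analysis

Gamete inference requires the tester to be homozygous for its most
recessive allele at every locus, which makes the informative parent's
gamete unique per progeny phenotype. Crossover classes are switch
patterns of homolog origin between adjacent loci under a candidate order;
interval RF is the switch frequency, which automatically reproduces the
classical "single + double + triple crossover" summation formulas. The
end-to-end RF between terminal loci is reported both as the *sum of
interval RFs* (the additive convention of the bundled study, 14.84% for
its four-locus table) and as the direct terminal switch frequency (always
≤ the sum; 13.58% there).

The bundled four-locus table carries a bookkeeping inconsistency in its
source: the 16 class counts sum to 1271 while the declared progeny total —
the sum of the two pooled population sizes, and the denominator behind
every published frequency — is 1267. `interval_rfs` therefore accepts a
declared total (the study config carries `n_declared: 1267`), defaults to
the class-count sum otherwise, and flags any mismatch in the result
rather than silently correcting either number.

Order search scores each of the n!/2 orientation-normalized orders by the
multinomial log-likelihood of the observed switch patterns with interval
fractions at their MLEs (the switch frequencies), assuming independent
intervals; ties break toward fewer multiple-crossover progeny, then the
shorter map. The reference criterion (minimize multiple crossovers) was
not stated as an algorithm in the source study, so likelihood ranking is
this package's design choice; on the bundled table all three criteria
agree, and on simulated data at the bundled table's parameters
(r = 0.0379/0.0047/0.1058, n = 1267) the generating order is recovered in
≥95% of 200 replicates.

Map distances: Kosambi m = 25 ln[(1+2r)/(1−2r)], Haldane
m = −50 ln(1−2r), with closed-form inverses (round-trip error < 1e-10,
verified). r ≥ 0.5 is a domain error (infinite distance). Positions are
cumulative from the first locus of the order and rounded (2 d.p.) only in
reports.

## Synthetic data

The simulator emulates the study's crossing designs: multinomial sampling
of class counts (one draw of size n from the exact class probabilities),
not per-meiosis simulation, for speed; a per-gamete enumeration path
exists inside the oracle and carries the interference model. The oracle
enumerates all 2^k homolog-origin vectors per parent explicitly and is
kept independent of the analytical gamete-distribution code, so the two
routes cross-check each other (agreement to 1e-12 is asserted).

Reproducibility: a `SimulationSpec` fully determines its output;
`replicate_study(templates, seed)` derives one sub-seed per template via
`numpy.random.SeedSequence(seed).spawn`, in template order — a stable,
documented splitting rule. Optional symmetric phenotype-misclassification
noise (off by default: the study's phenotypes were independently
confirmed, with no stated error model) replaces a locus's recorded label
with one of the other labels observable in that cross, uniformly, with
the given rate.

What the simulator does **not** emulate: viability selection or
segregation distortion (the bundled intercross tables show a
double-recessive excess relative to the pseudo-testcross r estimates that
the source proposes no mechanism for, and the simulator intentionally
does not reproduce it), linkage between the "unlinked" shape locus and
the map group beyond r = 0.5, and scoring error correlated across loci.
Passing calibration tests therefore show estimator correctness under the
stated model, not robustness to these real-data effects.

## Numerical conventions and problem sizes

* Class-probability sanity: distributions must sum to 1 within 1e-12.
* Phase/recombinant-class detection probes the forward model at r = 0 and
  r = 0.02 with a 1e-9 tolerance; ML search runs on [1e-9, 0.5−1e-9] with
  xatol 1e-10.
* Report precision: χ² and p to 3 d.p., RFs and map positions to 2 d.p.;
  internals keep full floats.
* Calibration tests use 200–500 replicates at n = 400–1267 (seconds on
  one CPU): estimator bias within 2 Monte-Carlo SEs at n = 1000 over 500
  replicates for r ∈ {0.01, 0.05, 0.15, 0.3}; simulator-vs-oracle GOF
  p-values checked uniform by Kolmogorov–Smirnov at alpha 0.01; type-I
  rate of the independence test within binomial bounds of alpha.

## Known limitations

Eight-plus-locus maps need a heuristic order search this package does not
provide. The f2 double-recessive design wastes the information in the
three ambiguous classes unless the ML estimator is chosen. Phase
inference needs a rejected independence test and therefore has no power
for loosely linked pairs in small progenies. The interference model is
limited to three-locus parents by construction.
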