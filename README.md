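# linkagekit

Classical (phenotype-based) Mendelian segregation and linkage analysis for
two-generation plant crosses: chi-square goodness-of-fit testing against
expected segregation ratios, parental genotype and linkage-phase inference,
two-point recombination-frequency estimation across cross designs,
multi-locus pseudo-testcross crossover classification with locus-order
search, and genetic-map construction with the Kosambi mapping function.

It is written for the setting in which no molecular markers are available
and every datum is a progeny phenotype-class count — the situation of
ornamental-plant breeding programs. The bundled worked study is the
inheritance of caladium (*Caladium* × *hortulanum*) leaf traits: background
color (*LEM*/*lem*), main vein color (*V*ʳ > *V*ʷ > *V*ᵍ), spotting
(*S*/*s*), rugosity (*RLF*/*rlf*) and codominant leaf shape (*F*/*f*), with
the full progeny counts of 19 crosses shipped as TSV fixtures.

## The statistics

**Segregation testing.** Observed class counts are tested against the
Mendelian ratio implied by a hypothesized parental genotype pair with the
uncorrected Pearson statistic χ² = Σ(O−E)²/E, df = classes − 1; parental
genotypes are inferred by enumerating all pairs compatible with the parent
phenotypes and ranking by p-value. Reciprocal crosses are compared by a
contingency χ² (a maternal-effect check).

**Two-point recombination.** For a doubly heterozygous parent crossed to a
double homozygote (pseudo-testcross/BC₁), every progeny reveals one gamete
and r̂ = (recombinant progeny)/n. For the intercross design segregating
3:3:1:1, only the double-recessive class is unambiguously recombinant; the
tabulated estimator is r̂ = 2 × (double-recessive count)/n, kept exactly as
published (a frequency-matching factor-4 variant and a bounded multinomial
maximum-likelihood estimator are available as overrides — see
`docs/methods.md`). Recombinant classes are identified from phase via the
forward model (a class is recombinant iff its probability vanishes at
r = 0), never hand-listed. Per-pair estimates from several crosses are
averaged unweighted with a sample SD.

**Multipoint.** Against a fully recessive tester, each four-locus progeny
phenotype is decoded to a parental gamete, traced to homolog origins, and
classified by its switch pattern (parental, single/double/triple crossover
with interval names). Interval RF = switch frequency; locus order is
searched over all n!/2 distinct orders by multinomial log-likelihood under
independent intervals. Map positions are cumulative Kosambi distances
m = 25 ln[(1+2r)/(1−2r)] cM (Haldane m = −50 ln(1−2r) optional).

**Simulator.** `synthetic_data` draws multinomial progeny counts from an
exact meiosis-enumeration oracle (per-interval r, optional coefficient of
coincidence for three-locus parents, optional phenotype-scoring noise),
fully determined by a seed.

## Worked example

The four-locus pseudo-testcross table (1267 progeny of 'Miss Muffet'
(*V*ʷ *s LEM rlf*//*V*ᵍ *S lem RLF*) × 'Candidum', pooled reciprocals):

```
$ linkagekit map four_locus.tsv
mapping_function=kosambi
cross t7-01: best order LEM-V-S-RLF
  RF(LEM-V) = 3.79%
  RF(V-S) = 0.47%
  RF(S-RLF) = 10.58%
  end-to-end (sum of intervals) = 14.84%
locus	position_cM	function
LEM	0.00	kosambi
V	3.80	kosambi
S	4.27	kosambi
RLF	15.01	kosambi
```

The best-ranked order places the background-color locus 3.80 cM from the
vein-color locus, with spotting 0.47 cM further and rugosity at the far
end of a ~15 cM map. The two-point stage on the spotting × background
tables prints, per cross, the independence χ², the inferred phase of the
informative parent, the estimator used and the per-cross and averaged RFs:

```
$ linkagekit linkage spotting.tsv
...
t4-04  S-LEM  ... 527.171  0.000  s LEM // S lem  testcross  spotted/lemon|non-spotted/green  3.45
...
S-LEM  6  5.37  2.15
```

i.e. spotting is linked to background color at an average 5.37 ± 2.15 %
recombination over six crosses, with the spotted allele *S* in coupling
with the green-background allele *lem*. The same calls are available as
library functions (`infer_phase`, `estimate_rf`, `search_order`,
`build_map`, ...); `linkagekit report` runs the whole chain and writes
TSV reports plus a MANIFEST.

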