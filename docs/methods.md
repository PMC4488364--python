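# Methods

## Model and estimators

For two diallelic loci scored on n unphased diploids, the sufficient
statistic is the 3×3 table of genotype counts n_ijkl (rows AA/Aa/aa,
columns BB/Bb/bb). All frequency estimates are maximum-likelihood counting
estimates. The package computes:

* **Zygotic LD** `D̂_ijkl = p̂_ijkl − p̂_ij p̂_kl` for all nine classes. The
  row and column families satisfy `Σ_i D_ijkl = 0` and `Σ_l D_ijkl = 0`
  identically (they are algebraic identities of the counting estimator, so
  the implementation checks them to 1e-12 rather than enforcing them). The
  four free coefficients D_AABB, D_AABb, D_AaBB, D_AaBb are each tested by
  `χ² = n D̂² / (p̂_Aj(1−p̂_Aj) p̂_Bl(1−p̂_Bl))` with 1 df; under
  independence the denominator over n is exactly Var(D̂), since D̂ is the
  sample covariance of two Bernoulli genotype indicators. The normalized
  statistic r² = χ²/n lies in [0,1].
* **Hardy–Weinberg disequilibrium** `D̂_A = p̂_AA − p̂_A²`, tested by
  `χ² = n D̂_A²/(p̂_A p̂_a)²` (equivalently n·f̂² with f̂ the fixation
  index), 1 df.
* **Composite digenic LD** by the counting definition
  `Δ̂ = 2p̂_AABB + p̂_AABb + p̂_AaBB + p̂_AaBb/2 − 2p̂_A p̂_B`, which is
  identically `2D̂_AABB + D̂_AABb + D̂_AaBB + D̂_AaBb/2` (note the
  coefficient 2 on the double-homozygote term: the counting definition
  forces it, and the identity is asserted to 1e-12 on every table). Δ̂
  equals the gametic LD when genotypes are formed by random union of
  gametes; more generally it adds the within-individual between-gamete
  disequilibrium and needs no phase or random-mating assumption.
* **Difference statistic** `d̂ = |Δ̂| − max(|D̂_AABB|, |D̂_AABb|,
  |D̂_AaBB|, |D̂_AaBb|)`. A pair whose composite association is carried by
  one dominant zygotic LD — the double-heterozygote excess with Δ ≈ 0 being
  the canonical case — gives d̂ significantly below 0 and is classified
  **epistatic**; d̂ significantly above 0 is classified **additive**;
  otherwise **weak**. The argmax genotype and its sign are recorded; ties
  break by the fixed order AABB, AABb, AaBB, AaBb. The "sign case" is
  *same* when Δ̂ and the argmax LD share a sign, *opposite* otherwise.

## Variance of Δ̂ and its chi-square test

The closed-form variance bracket implemented is

    n·V(Δ̂) = Δ̂(1 − Δ̂ − 2(p̂_A + p̂_B − 4 p̂_A p̂_B))
            + (p̂_A p̂_a + D̂_A)(p̂_B p̂_b + D̂_B)
            + 2D̂_AABB − D̂_AaBb/4
            − 4p̂_A(D̂_AABB + D̂_AaBB/2) − 4p̂_B(D̂_AABB + D̂_AABb/2)

The grouping of the `2D̂_AABB − D̂_AaBb/4` term is typographically
ambiguous in print; we verified symbolically (sympy) that this reading is
**exactly** the first-order delta-method variance of Δ̂ under multinomial
sampling of the nine classes — the gradient of Δ̂ in the class proportions
propagated through the exact multinomial covariance — while the alternative
grouping `(2D̂_AABB − D̂_AaBb)/4` is not, and fails the Monte-Carlo
comparison (it can even go negative). The alternative remains available via
`variance_reading="quarter"` for sensitivity analysis. The test statistic is
`χ² = Δ̂²/V(Δ̂) = n Δ̂²/bracket`, 1 df; writing the test this way keeps
χ² asymptotically chi-square (the bracket is the variance of √n·Δ̂, the
same convention as the zygotic χ² denominator).

**Zeroing protocol.** Under H0 the Δ̂ term in the bracket is set to zero;
each zygotic LD and each HWD term is dropped (zeroed everywhere it appears)
unless individually significant at the working α. When every optional term
drops, the bracket reduces to `p̂_A p̂_a p̂_B p̂_b`, the null variance of
n·Δ̂. If the substitutions leave a nonpositive bracket the test is not
performed and the record is flagged with a diagnostic. r²_Δ = χ²/n; the
substitutions can push it above 1 in pathological tables, which is flagged
rather than silently clipped.

## Variance of d̂

The variance of d̂ is estimated by a **generic plug-in multinomial delta
method**: the gradient of `d = sign(Δ)·Δ − sign(D_m)·D_m` in the nine class
proportions, evaluated at the observed table with the argmax component m
held fixed, propagated through the exact multinomial covariance
(`V = (Σ p c² − (Σ p c)²)/n`). The quadratic form is already centered, so
the protocol's "d set to zero in V" needs no extra substitution; component
statistics enter as plug-in observed values. A **nonparametric bootstrap**
(n individuals resampled from the empirical nine-class distribution,
default B = 2000, seeded) serves as oracle and fallback. The delta method
falls back to the bootstrap, with a recorded diagnostic, when (a) the top
two |D̂| tie (d̂ is not differentiable there) or (b) the gradient variance
is nonpositive (e.g. the two-class AABB/aabb table, where d = p(1−p) is
stationary at p = ½). `difference_d_test(..., method="bootstrap")` selects
the bootstrap outright. An alternative closed-form variance, should one be
preferred, can replace the default by post-processing scan records with any
callable that maps a table to a variance; the delta/bootstrap pair is the
shipped, validated implementation.

**Validity domain.** The delta method linearizes |Δ̂| and max|D̂|, so it
requires both to sit away from their kinks: |Δ| and the gap between the top
two |D| each at least ~3 sampling SEs at the working n. The validation
suite (`d_method_validation_models`) therefore draws tables from coupling,
admixture and drift-like models with argmax gaps ≥ 0.03 at n = 1000 —
which is also the only regime the scan ever reaches stage 3 in, since the
zygotic gate at α = 10⁻⁹ admits essentially no null-like pairs. On the
epistatic signature model (Δ = 0 exactly) the delta method overestimates
Var(|Δ̂|) by up to ~2.7× (folded-normal effect); this does not affect
classification in practice because planted epistatic pairs have |d̂| tens
of SEs from 0, but users probing near-fold tables should request the
bootstrap.

## Staged scan protocol

Per syntenic pair within the window (default 10 Mb, boundary inclusive;
pairs enumerated per chromosome in position order):

1. Test the four tracked zygotic LDs and both HWDs at α (default 10⁻⁹,
   chosen as a Bonferroni-conservative genome-wide level).
2. Only if ≥1 zygotic LD is significant, test Δ̂ with the zeroing protocol.
3. Under the same gate, test d̂ and classify.

n is recomputed per pair over pairwise-complete individuals (non-missing at
both loci), so n varies across pairs of one panel. Pairs monomorphic after
missing-data exclusion are flagged unusable and excluded from summaries.
n < 30 triggers a warning (delta-method variances are first-order
asymptotic and unstable in small samples; the same caution applies to
low-MAF pairs, whose rare-cell chi-squares are conservative — see
calibration below). Output is a streamed TSV keyed (chrom, pos1, pos2),
deterministic for a fixed config seed (per-pair bootstrap seeds derive from
`SeedSequence((seed, pair_index))`), with memory independent of the pair
count.

## Genotype IO

HapMap phase III genotype text files (space- or tab-delimited; 11 fixed
header columns then sample IDs; missing token `NN`). Recoding to one
diallelic locus uses the fixed letter-precedence rule A > C > G: the
highest-precedence allele of the SNP's pair is the reference (homozygote
code 2, heterozygote 1, other homozygote 0). Heterozygote letter order is
normalized; strand is parsed but ignored (the rule operates on printed
letters); rows with letters outside the declared allele pair are skipped
and logged with line numbers. The writer emits the reference homozygote
with the same precedence rule, making write→read the identity on codes.
MAF filtering (default: keep MAF ≥ 0.05, inclusive, per population,
computed from non-missing codes) runs *after* cross-population rsID
intersection — the pipeline order; the two orders do not commute and a test
demonstrates the difference. The reader exposes an optional
sample-exclusion list (e.g. known relatives) with no default policy, since
no authoritative policy exists for the source panels.

## Synthetic data

`TwoLocusModel` holds the nine true class probabilities; constructors build
it from four free zygotic LDs plus marginals (the other five by the
constraints; infeasible probabilities raise) or from haplotype frequencies
under random union of gametes (then Δ_true = D_AB exactly and marginals are
Hardy–Weinberg). Scenario defaults:

* `null`: independent loci, HWE, MAF 0.3.
* `coupling`: haplotype model, p_A = p_B = 0.5, D_AB = 0.2 (strong but
  sub-maximal gametic coupling).
* `drift_homozygote`: 10–40% of mass moved onto AABB/aabb — the
  double-homozygote excess that drift/bottlenecks and inbreeding generate;
  default excess 0.1, validation suites use 0.3–0.4 so the additive signal
  is unambiguous at n = 2000.
* `admixture`: equal mixture of two internally-HWE subpopulations with
  allele frequencies 0.2/0.8 (Wahlund-type association).
* `epistatic_heterozygote`: D_AaBb = 0.24 with D_AABB = 0.06,
  D_AABb = D_AaBB = −0.12, arranged so Δ = 0 exactly — the corner table
  (0.1 in each double homozygote, 0.6 double heterozygote) used throughout
  as the epistatic-selection signature.

`simulate_chromosome` draws background SNPs independently at HWE with MAF
uniform on a configurable range (default 0.1–0.5, matching a
common-SNP panel after a 5% MAF filter), overwrites declared pairs with
joint draws from their models, assigns strictly increasing positions and
random allele-letter pairs, and optionally injects missingness uniformly at
random (the missing rate is a free parameter; it exercises the
pairwise-complete policy). Background independence makes null
rejection-rate suites exact. What the generator does **not** emulate:
LD decay along the chromosome (background SNPs are unlinked), allele
frequency spectra of real populations, genotyping-platform error, or
relatedness structure — so passing tests demonstrate correctness of the
estimators and protocol, not robustness to those real-data features.

## Calibration and validation (computed by the test suite and
`scripts/acceptance.py`)

* Constraint families and the Δ̂ decomposition identity: 1e5 random
  multinomial tables, 1e-12.
* Δ̂ vs true gametic LD on random-mating populations: 100 random feasible
  haplotype models, n = 1e5.
* Type-I error at α = 0.05, n = 200, 2e4 replicates, MAF 0.3 at both loci
  with the reference allele minor at one locus and major at the other, so
  every tracked genotype cell has expectation ≥ 5 (the chi-square validity
  regime). With both reference alleles minor the AABB cell has expectation
  ≈ 1.6 and its test is conservative (empirical size ≈ 0.039) — the
  small-sample caution above, quantified.
* Closed-form composite variance vs Monte Carlo (n = 1000, 5000 replicates, three
  scenarios) — also the experiment that selects the literal parenthesization.
* Delta-method vs bootstrap V(d̂) on 200 tables from the validation models.
* Power ≥ 90% for planted additive (drift, excess 0.3) and epistatic pairs
  at n = 2000, α = 10⁻⁹; zero epistatic calls on a 19,900-pair null
  chromosome at n = 200.
* Exact recovery of 7 epistatic pairs planted in all of 3 populations;
  Canberra clustering of two planted vector groups with BP ≥ 95.

Problem sizes throughout (2e4 calibration replicates, 5000-replicate
Monte Carlo, B = 2000 bootstrap, 200-SNP null chromosome, n = 2000 panels)
are the package's validation defaults: large enough that Monte-Carlo error
is well below every tolerance checked, small enough to run interactively.

## Summaries and population comparison

Per population, seven categories of significant records (four zygotic, Δ,
d > 0, d < 0) are summarized by count, mean ± SD of r², mean and CV
(SD/mean) of pairwise distance in Mb, and the Pearson correlation between
significant r² and distance (two-sided p via the t transform; flagged
undefined below 3 records or at zero variance). The population feature
vector is 20-dimensional — the five non-d categories × (count, mean r²,
mean distance, distance correlation), category-major; d categories are
excluded, and per-category (not pooled) counts are required to reach 20
dimensions. Cross-population epistatic intersection keys pairs by sorted
rsID pair and requires significant d < 0 in every table. Clustering uses
the Canberra distance `Σ_k |x_k − y_k|/(|x_k| + |y_k|)` (0/0 terms
contribute 0) on raw features — Canberra is scale-aware by construction, so
no standardization — with average linkage (the common default of the cited
clustering tooling; configurable) and plain bootstrap proportions from
resampling the 20 features with replacement; approximately-unbiased
multiscale-bootstrap p-values are out of scope. The dendrogram is exported
as Newick with BP labels on internal nodes.

## Known limitations

* All tests are first-order asymptotic; results for n < 30 or rare
  genotype cells are unstable/conservative, and the extreme α = 10⁻⁹ tail
  is further from the chi-square approximation than moderate tails
  (observed as occasional spurious stage-2 gating on null data at small n —
  never spurious epistatic calls in our suites).
* Gametic LD is deliberately not estimated (no EM phasing); the composite
  LD is the phase-free object of inference.
* Pairs are intra-chromosomal within the window only; multi-allelic sites,
  X/Y chromosomes, kinship filtering and annotation are out of scope.
* The bootstrap-proportion clustering reports plain BP, which is known to
  be biased relative to AU p-values for deep clusters.
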