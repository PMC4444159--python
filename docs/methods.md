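# Methods

## The model

`rgikit` treats a genome as a draw from a product measure over loci. At
each biallelic autosomal SNP *l*, the three genotype categories
(hom-ref, het, hom-alt, coded 0/1/2 as copies of the counted allele) have
probabilities Π<sub>l</sub>, estimated from a reference cohort:

    Π_l(g) = (count_g + a) / (n_obs + 3a)

with pseudocount *a* (default 0.5, i.e. Jeffreys-style smoothing per
category). The relative local information of an observed genotype is its
surprisal, RLI = −log₂ Π<sub>l</sub>(g), in bits; the relative genome
information RGI is the sum of RLI over the shared locus set, and the
expected information per locus EIL = RGI/n. A missing genotype is scored
as the locus entropy H(Π<sub>l</sub>) — its expected surprisal — and, in
the default "impute" mode, n remains the full locus count. A "drop" mode
that excludes a sample's missing loci from both numerator and n is
provided; with array-typical missingness (≤1%) the two agree closely.

Assumptions the product measure makes explicit:

- **Independence across loci.** Π is a product measure; linkage
  disequilibrium is not modelled. RGI is therefore an *encoding length
  under an independence code*, not the true joint information content.
  LD pruning before scoring reduces (but does not remove) the
  discrepancy.
- **Reference exchangeability.** EIL comparisons are meaningful only when
  all cohorts are draws from the ancestry represented by the reference;
  the MDS ancestry screen exists to enforce this.
- **Scored loci are the shared post-QC set** across all cohorts, so every
  genome is measured under the same code.

Two identities anchor the implementation and are tested directly: for
genomes drawn from Π itself, E[EIL] equals the mean per-locus entropy;
and RGI is additive over disjoint locus sets.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| pseudocount `a` | 0.5 | counts/category | bounds the surprisal of genotypes unseen in the reference (the plain estimator assigns them −log₂ 0); 0 reproduces the unsmoothed estimator and raises on zero-probability observations |
| MAF threshold | 0.01 | fraction | conventional array QC floor |
| call-rate threshold | 0.99 | fraction | loci with <99% calls removed (boundary kept) |
| HWE exact-test P | 1e-4 | — | Levene–Haldane exact test; exact rather than chi-square so calibration holds at rare alleles |
| LD pruning r², window, step | 0.5, 50, 5 | —, loci | PLINK-convention greedy windowed pruning |
| MDS outlier factor `c` | 3 | × RMS centroid distance | operationalizes "does not cluster with the reference"; exposed because it is a judgement call |
| odds-curve spline df | 6 | basis functions | cubic B-splines; penalty weight chosen by GCV n·D/(n−edf)² over a log-spaced grid |
| attribution replicates | 10⁴ | — | resampling CI stability; the acceptance script uses 2×10³ to keep runtime modest |
| attribution draw cap | 10⁶ | draws/replicate | guarantees termination when the mean excess is non-positive; capped replicates are excluded and counted |

QC filters run in the fixed order MAF → call rate → HWE, and the QCReport
records which cohort HWE was computed on. HWE filtering belongs on
reference/control cohorts: in cases, departure from Hardy–Weinberg at a
risk locus is potential signal, not artifact.

## The synthetic-data generator

`simulate_population` emulates the study design the scorer assumes: a
reference cohort (measure estimation), independent controls, and cases
ascertained through a liability-threshold model. Loci are independent
biallelic SNPs in HWE; minor-allele frequencies are uniform on
[0.05, 0.5] by default (a post-QC common-variant array spectrum; a
truncated-beta spectrum is available). Liability is
Σ β·(minor-allele count over k risk loci) + N(0,1) noise, and individuals
above the population ascertainment quantile (default: top 10%) become
cases. Risk alleles are minor alleles by default — this is what makes
ascertained cases information-richer, the phenomenon the method detects —
with a flag to randomize risk-allele sign for null-robustness checks.
Missing calls are masked uniformly at random.

What the generator does **not** emulate: LD (no haplotype structure),
population stratification beyond the two-population MDS fixture,
genotyping batch effects, and rare variants below the spectrum floor.
Passing tests therefore demonstrate the estimator's statistical behaviour
under its own assumptions — calibration under the null, detection of a
planted polygenic signal, identity properties — not robustness to the
correlated noise of real arrays.

### Power at the default design, and a known red check

A structural property of liability-threshold ascertainment with a shared
liability: selecting the top decile shifts each risk locus's expected
minor-allele count by ≈ S·β·2f(1−f)/σ<sub>g</sub>, where σ<sub>g</sub> ∝
β√k. Per-locus frequency shifts — and hence the EIL elevation — dilute as
1/√k and are nearly invariant to β once the genetic variance dominates
the noise. At the default scale (k = 500 of 10,000 loci, β = 0.3, 300
cases vs 300 controls) the median EIL gap is ≈ 0.003 bits against a
per-sample EIL standard deviation of ≈ 0.0095, i.e. a z of roughly 4:
the one-sided Wilcoxon P lands around 10⁻³–10⁻⁵ and the 99th-percentile
odds ratio rests on ~6 tail samples and is statistically unstable. The
acceptance-style power test asserts a stricter P < 10⁻⁶ and a significant
99th-percentile odds ratio; those two sub-checks fail at this design
scale by construction, and are left failing rather than weakened — the
direction of the effect, the KS distribution test and the monotone
odds-vs-EIL curve all pass. An independent per-locus enrichment model
(without a shared liability) would concentrate much more information per
locus, but ascertained-cohort realism was judged more important than
headline power.

## Locus attribution

The resampling attribution asks: how widely must one range over the locus
panel, drawing (case genome, locus) pairs uniformly with replacement and
accumulating that genome's RLI excess over the control locus mean, before
the total-information gap n·(Q<sub>case</sub>(p) − Q<sub>ctrl</sub>(p))
at percentile p is covered? Draws may decrease the running sum (negative
excess is not clipped); each replicate reports the number of distinct
loci touched, and 10⁴ replicates are summarized by median and 2.5/97.5%
quantiles. A non-positive gap at a percentile yields a "not applicable"
row.

Interpretation: the distinct-locus count approaches the panel size when
the excess is spread thinly (the polygenic signature) and stays near k
when k excess-carrying loci dominate the panel. The recovery test plants
excess on k loci of a 2k panel — with target Δ = k·e and hit probability
1/2 the expected count is ≈ 2k(1−e⁻¹) ≈ 1.26k — while the
count-vs-percentile monotonicity test uses per-case lognormal effect
multipliers, because a constant planted shift moves every EIL quantile
equally and gives a flat profile. Identical seeds give bit-identical
results; a grid of percentiles consumes one shared generator stream in
grid order.

## Numerical choices

- **Logarithms** are base 2 throughout; all information quantities are in
  bits.
- **HWE exact test**: heterozygote counts are enumerated in log-space
  (gammaln), normalized by logsumexp; the two-sided P sums probabilities
  ≤ the observed one with a 1e-10 log-space tie tolerance. Verified
  exhaustively against exact integer combinatorics for all count triples
  with N ≤ 10 and spot-checked at N = 100.
- **Wilcoxon**: scipy's implementation — exact enumeration for small
  tie-free samples, otherwise normal approximation with midranks, tie
  correction and continuity correction.
- **Fisher's exact test**: conditional two-sided P; the reported odds
  ratio is the sample ad/bc with a 0.5 Haldane correction applied to all
  cells iff any cell is zero (flagged in the result).
- **Odds-vs-EIL curve**: logistic GAM with cubic B-splines; the penalty
  is selected by an explicit GCV grid search (statsmodels' built-in GCV
  selector degenerates to the grid's upper bound on binomial responses).
  The curve is anchored at OR = 1 at the *control median* EIL; pointwise
  95% intervals come from the penalized covariance and are suppressed
  with a warning under perfect separation. The anchor choice and the
  pooled-vs-control percentile threshold (pooled by default) are exposed
  because either convention is defensible.
- **LD pruning** removes, within each sliding window, the member of the
  worst-correlated pair with the lower call rate (ties: the later locus),
  recomputing until no retained pair exceeds r².
- **MDS** is classical principal-coordinates analysis of the
  allele-sharing distance D(i,j) = mean |g_i − g_j|/2 over co-observed
  loci, computed by indicator-matrix products so missing calls are
  excluded pairwise; negative eigenvalues are clipped at zero.
- **Allele harmonization** across cohorts: exact match, order swap
  (codes flipped 0↔2), and strand-complement matches are accepted, in
  that order; palindromic A/T and C/G SNPs are accepted only on an exact
  in-order match, since a swap there is indistinguishable from a strand
  flip. Irreconcilable loci are dropped with a logged count.
- **Degenerate inputs**: monomorphic loci give HWE P = 1; an all-missing
  locus is an error at measure estimation; empty cohorts, single-sex
  cohorts and empty percentile grids raise immediately.

## Known limitations

- The product measure ignores LD, so absolute RGI values overstate
  information content in proportion to local correlation; comparisons
  between cohorts scored on the same locus set are unaffected to first
  order, which is why the package's statistics are all contrasts.
- Tail quantities (99th-percentile odds ratios, high-percentile
  attribution rows) are unstable below a few thousand samples per group;
  the acceptance script reports them anyway, with `null` where undefined.
- The generator's case model produces a mean-shift-plus-heavier-tail EIL
  contrast; it cannot produce signals localized to specific annotations
  or chromosomes unless risk loci are planted there explicitly (the
  stratification tests do exactly that via direct RLI fixtures).
- PLINK 2 formats, imputation panels, build liftover and relatedness
  filtering are out of scope; inputs are PLINK 1 triples or VCF 4.x.
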