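# Methods

## Model

For q individuals (a mixture of pedigree members and unrelateds) with
quantitative trait y, covariates X and a genotyped region of n variants, the
working linear mixed model is

    y = Xβ + g + δ (+ α) + ε,
    Var(y) = S σg² + A σδ² (+ C σα²) + I σε²,

where

* **S** is a region similarity matrix — by default the linear similarity
  S = Z Z'/n on genotypes standardized as z = (s − 2f)/√(2f(1−f)), f being
  the minor allele frequency.  A weighted identity-by-state kernel
  K_ij = Σ_l w_l (2 − |s_il − s_jl|) with optional beta-density weights
  w_l = Beta(p_l; a, b), or a haplotype-sharing matrix summing a
  haplotype-level similarity over the four cross-individual haplotype pairs,
  can be substituted for S unchanged;
* **A** is the background genetic similarity: a genome-wide GRM
  Z_gw Z_gw'/N (with the tested region excluded) or, for pedigree data,
  twice the kinship matrix 2Φ computed by the standard recursion
  φ_ii = ½(1 + φ_fm), φ_ij = ½(φ_{i,f(j)} + φ_{i,m(j)});
* **C** is an optional 0/1 same-household indicator (block of ones per
  family, diagonal included) absorbing shared-environment variance.

The association question is H0: σg² = 0, a variance-component boundary test.

## Null fit

The nuisance model y = Xβ + δ (+ α) + ε is fitted by ML or REML (REML is
the default).  Without C, the likelihood is profiled on the ratio
γ = σδ²/σε² after one eigendecomposition of A, leaving a 1-D bounded Brent
search on log γ ∈ [−15, 15] (profiling β and σε² in closed form); with C, a
quasi-Newton (L-BFGS-B) search runs on log-variances with a tight objective
tolerance (1e-13 relative) so the two paths agree to ~1e-4 relative on
variance components.  Variances are kept non-negative by the log
parameterization; a component pinned at the boundary is flagged because the
score test's moment corrections assume interior estimates.  y and covariate
columns are mean-centered by default; fitting is deterministic.

Block structure is exploited throughout: for family data A, C and V0 are
block diagonal under a family-sorted order, and all solves, log-determinants
and trace contractions run as batched small-matrix operations, so one
replicate at q = 5,000 costs well under a second.

## Score test

With η̂ the null estimates and V0 = Aσ̂δ² (+ Cσ̂α²) + Iσ̂ε², the score for
σg² is U = −½tr(W S) + ½ r'W S W r with r = y − Xβ̂ and W = V0⁻¹ (ML) or the
REML projection P0 = V0⁻¹ − V0⁻¹X(X'V0⁻¹X)⁻¹X'V0⁻¹.  The test statistic is
the quadratic part T = ½ r'W S W r, distributed under H0 as Σ λ_i χ²_{1,i}
with λ_i the nonzero eigenvalues of ½ W^{1/2}-conjugated S; for a low-rank
factorization S = FF' these are the eigenvalues of ½F'WF, an n×n problem.
Useful identities asserted in the tests: Σλ_i = μ_T = ½tr(W S) and
2Σλ_i² = ν_T = ½tr((W S)²).

Four p-value routes:

* **empirical** — Monte Carlo draws of Σλχ², add-one estimator
  (1 + #{≥T})/(B+1); seed mandatory;
* **satterthwaite** — Gamma(μ²/ν, ν/μ) (identically, a scaled chi-square).
  ν is replaced by the efficient information
  I_τ = I_ττ − I_τη I_ηη⁻¹ I_ητ ("partial information") to account for
  estimated nuisance variance parameters; if I_ηη is singular (e.g. A = I
  makes σδ² and σε² aliased) the uncorrected variance is used with a
  warning;
* **liu** — three/four-moment matching to a (noncentral) chi-square using
  the original skewness-matching rule; accurate to ~2e-3 near the 5% tail
  and validated against Monte Carlo at the 1% tail;
* **davies** — numerical inversion of the characteristic function by
  Gil-Pelaez quadrature (head interval by adaptive quadrature, tail by
  oscillatory-weight QUADPACK against the linear phase), absolute accuracy
  ~1e-9; the reference method.  Below ~1e-10 the inversion hits its
  absolute-accuracy floor and the moment-matching value is the better
  guide.

Eigenvalues below 1e-10·λ_max are treated as zeros.  An r-truncation of the
spectrum is available but off by default.

The FGLS comparator augments X with a burden column (raw or standardized
minor-allele sum), plugs in V0 estimated once under the global null, and
Wald-tests the burden coefficient.  When S is the rank-1 outer product of
the burden column, the REML score test and FGLS produce identical 1-df
chi-square p-values (verified to 1e-13).

## Synthetic data

The generator reproduces the study conditions used to characterise the
test:

* **Pool** — 10,000 haplotypes over 500 kb from a neutral coalescent
  (msprime; diploid samples, Ne = 10⁴, μ = 1.5e-8 /bp/gen), recombination
  piecewise-constant over 100 kb windows with rates drawn log-normally
  (σ = 0.7) around a mean of 1e-8 /bp/gen — the human genome-average scale
  with regional variation.  This yields ≈2,900 segregating sites of which
  ≈66–73% have MAF < 0.05 (Watterson expectation ≈2,936; neutral folded-SFS
  expectation ≈0.70).
* **Risk model** — a contiguous 500-variant window is chosen uniformly;
  causal sites are drawn in random order from the window's MAF < 2% sites
  until the frequency of risk haplotypes (those carrying a minor allele at
  any causal site) reaches 10%; typically ~5–10% of window variants end up
  causal.  An ascertainment surrogate removes 2,000 non-risk haplotypes
  from the founder pool, raising the founder risk frequency to ≈1/8.
* **Cohorts** — founders/unrelateds draw two haplotypes with replacement;
  children per family ~ Poisson(2); each child inherits one whole parental
  haplotype per parent (no within-region recombination).  Haplotypes
  collapse to unphased genotypes.
* **Phenotypes** — y = g + p + e, centered.  g = u·z with z the
  risk-haplotype count and u = √(h²/(2r(1−r))) so var(g) = h² on the unit
  total-variance scale (r is the realized pool risk frequency); var(p) =
  0.4 − var(g), var(e) = 0.6.  Children's polygenic values are
  p_c = ½(p_m + p_f) + ½p_i with p_i ~ N(0, var(p)) — the "faithful" mode,
  var(p_c) = ¾var(p) — or a variance-preserving mode using √½·p_i.
  Analyses of simulated data use A = 2Φ.

What the generator does **not** emulate: the demographic history of real
human populations (bottlenecks and recent explosive growth), mutation-rate
heterogeneity, genotyping error, and ascertainment beyond the founder-pool
enrichment.  Passing the simulation-based checks therefore demonstrates
correctness of the statistical machinery under neutral constant-size
coalescent genetic architecture, not performance on real sequence data.

## Study driver and problem sizes

`run_study` redraws the risk assignment, cohort and phenotypes each
replicate (fixed pool), analyses each replicate with the REML score test
over the 500-variant region, and tabulates rejection rates with binomial
Monte Carlo standard errors.  Design presets: primary 500 families/2,000
unrelated; I 500/3,000; II 750/2,000; III 750 (enriched founders)/2,000.
The packaged studies use 2,000 null replicates (100 families + 400
unrelated) for type-I error and 200 replicates per design for power — the
published replication count — with one common replicate seed across designs
so design contrasts are paired.  All randomness descends from explicit
master seeds via spawned substreams.

## Known limitations and observed behaviour

* Exact (characteristic-function) p-values and the two-moment gamma
  approximation diverge deep in the tail: the gamma tail is lighter, so at
  thresholds like 1e-5 it reports smaller p-values than the exact mixture.
  Under the simulated conditions (constant-Ne pool, h² = 0.01, q = 5,000)
  the exact-inversion power at α = 1e-5 is small (a few percent), while the
  Satterthwaite route reports ~0.12–0.18.  Published power values at such
  thresholds are approximation-sensitive, and reproducing them requires the
  same demography and the same tail approximation.
* Power at α = 0.05 under the constant-size neutral pool measures ≈0.69–
  0.75 for all three large designs at h² = 0.01 — below the published
  0.84–0.94 from a calibrated human-demography pool; the gap is a property
  of the haplotype pool (frequency spectrum and LD of causal variants), not
  of the test statistic, whose calibration under H0 is verified directly.
* With A = I (all unrelated, no GRM) σδ² and σε² are aliased; only their
  sum is identifiable and the information correction degrades gracefully.
* The weighted-IBS kernel builder is dense (O(q²n)) and intended for
  moderate cohorts; the linear-similarity path is the scalable one.
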