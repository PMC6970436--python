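# Methods

## Model and statistic

For a trio (variant L, cis gene C, trans gene T) on n samples, three
ordinary-least-squares models are fitted with intercepts:

    C = a1 + b1*G + Cov*g1 + e1
    T = a2 + b2*G + Cov*g2 + e2
    T = a3 + b3*C + b4*G + Cov*g3 + e3

G is the additive dosage of L (0/1/2 allele counts; at least two genotype
classes required, otherwise the variant is untestable).  The mediation
statistic is the t statistic z = b3/se(b3) of the cis transcript in the third
model; testing is two-sided throughout (absolute statistics are compared).
Errors are assumed Gaussian and homoscedastic; the expression matrix is
assumed already normalized (the package does no normalization).

Numerics: the design is assembled as [1 | C | G | Cov]; collinear columns
are dropped deterministically (first occurrence kept, Gram–Schmidt residual
test at relative tolerance 1e-10) with a warning, the system is solved by QR,
and a condition number above 1e10 triggers a warning.  When se(b3)
underflows (e.g. T equals C exactly), |z| is capped at 1e8 and the fit is
flagged degenerate instead of returning infinity.  Missing data are handled
per trio by complete-case removal of samples missing G, C, T, or any
covariate.

## Permutation null

The null distribution of z is characterized by shuffling the cis-transcript
values independently within each genotype class, which destroys any C→T
mediation while preserving both eQTL associations and the covariate
structure; T and the covariates are never permuted.  Exceedances are counted
with ties included (|z0| ≥ |z|), the conservative convention.

Permutation statistics are computed by a residualization fast path: T and
each permuted C are projected off the orthonormal basis of [1, G, Cov] once
per trio, after which the full-model t statistic for C is a ratio of inner
products (Frisch–Waugh).  The identity with the full refit is exact for
full-rank designs and is verified to 1e-10 in the test suite.  Batches of
permutations are evaluated as single matrix products; permutations within a
batch are generated by argsorting random keys within each genotype stratum.
Permutations whose fit degenerates are recorded as failures; more than 10%
failures aborts the trio.

### Estimators

* Fixed: p = (M+1)/(N+1) after exactly N permutations (pseudo-count avoids
  p = 0); the attainable minimum is 1/(N+1).
* Adaptive: with pruning threshold K = ⌊αN⌋ (minimum 1; α = 0.05, N = 10,000
  default so K = 500), the stream stops at the first permutation index Γ at
  which the running exceedance count reaches K, or at N.  p =
  min(K+1, M+1)/min(Γ+1, N+1).  Batches of 100 are drawn at a time, but batch
  ends are scanned element-wise so the reported Γ is the exact stopping
  index.  When no early stop occurs the estimator coincides with the fixed
  one on the same stream.
* GPD tail: see below.

Per-trio RNG substreams are derived from (base seed, trio index) via
`numpy.random.SeedSequence`, so serial and parallel runs, and fixed vs
hybrid schemes on the unstopped prefix, consume identical streams (both
batch at 100).

## Generalized-Pareto tail approximation

Sort the executed null statistics decreasingly, pick the top Nexc, set the
threshold t to the midpoint of the Nexc-th and (Nexc+1)-th values, and fit
the exceedances x = z0 − t with the GPD

    F(x) = 1 − (1 − k x / a)^(1/k)   (k ≠ 0),    F(x) = 1 − exp(−x/a)   (k = 0),

scale a > 0; for k > 0 the support is bounded at a/k.  This k is the negated
shape of the common ξ convention (scipy's `genpareto` c = −k); the conversion
happens only at test boundaries.  The tail p-value is

    p = (Nexc / N) · (1 − F(|z| − t)),

valid only when |z| > t.  If |z| − t exceeds the support bound of a k > 0
fit, the p-value is exactly 0; it is reported as 0 with a machine-readable
`beyond_support` flag plus the upper bound (Nexc/N)·1e-12, which downstream
q-value computation substitutes for the zero.

Maximum likelihood uses the profile likelihood over θ = k/a, for which the
conditional estimates are closed-form (k̂ = −mean log(1 − θx), â = k̂/θ): the
profile is scanned on a 301-point grid (augmented with the method-of-moments
point) and refined by bounded Brent search; k̂ is restricted to ≤ 0.95 to
avoid the degenerate likelihood spike as θ → 1/max(x).  Constant exceedances
or an empty admissible region return a flagged failure, never an exception.

Goodness of fit is the Anderson–Darling A² of the exceedances against the
fitted CDF.  Because both parameters are estimated, the critical values are
not distribution-free in the usual sense; they depend on k.  The critical
value table (levels 0.5 … 0.001, shapes −0.5 … 0.9) was generated once by
parametric Monte Carlo — 20,000 replicates of 1,000 GPD exceedances per
shape, parameters re-estimated on each replicate by the same ML routine —
and frozen as a module constant.  P-values interpolate linearly in k (clamped
to the tabulated shape range) and log-linearly across levels; values beyond
the table are reported as the nearest tabulated level, which is sufficient
for the 0.05 acceptance gate.

The tail-fitting loop starts at Nexc = min(250, executed − 1) and accepts the
first fit with GOF p > 0.05, otherwise reduces Nexc by 10; below a floor of
10 exceedances (our choice; ties at the threshold are floored at 1e-12) the
GPD path is declared failed and the caller falls back to the fixed estimator
with a `gpd_failed` flag.

Routing (`p_hybrid`): if the adaptive rule already stopped early, its p-value
stands.  Otherwise the GPD path is attempted when M < Γ·α_gpd (α_gpd = 0.01
default, ties counted as in the fixed scheme); otherwise the fixed estimator
is used.  The executed permutation count Γ may be less than N when the
adaptive scheme supplied the stream.

## Confounder adjustment

Known covariates always enter Cov.  Hidden covariates come from a pool:
either user-supplied factors (PCs, surrogate variables, PEER factors — not
recomputed here) or, by default, the top 30 principal components of the
gene-by-sample expression matrix (gene-wise centering, SVD, deterministic
sign: the largest-magnitude loading of each component is positive).  The pool
is built once on the full matrix.

* Fixed adjustment: the whole pool enters Cov for every trio.
* Adaptive adjustment: per trio, each pool component is Pearson-correlation
  tested against C and against T; Benjamini–Hochberg is applied across the
  2·n_pool tests and a component is kept if either test is significant at
  FDR 0.05 (configurable).  The rule is deterministic and an empty selection
  is valid.  This operationalizes "select pool components correlated with C
  or T"; selection heuristics that additionally screen components against
  the genotype (to avoid adjusting away mediators) exist elsewhere and are
  intentionally not replicated — users wanting a different rule can pass a
  pre-filtered pool.

Every scheme combines with every adjustment mode; the test suite enforces
the full compatibility matrix.

## Multiple testing across gene pairs

Per gene pair, the best trio is selected (by nominal mediation p-value by
default, or by cis-association p; ties break on lexicographic variant id) and
Storey–Tibshirani q-values are computed on the best trios' permutation
p-values.  π0 is estimated on the λ grid 0.05…0.95 (step 0.05) with a cubic
smoothing spline evaluated at λ = 0.95 and clipped to (0, 1]; with fewer than
100 p-values or a non-positive spline value the fallback min(1, 2·mean(p)) is
used with a warning.  Forcing π0 = 1 reproduces Benjamini–Hochberg exactly.
Default discovery thresholds: suggestive permutation p ≤ 0.05, significant
q ≤ 0.25.

Candidate trios are built by joining cis associations (FDR ≤ 0.05; BH
computed if the table lacks an FDR column) with trans associations
(p < 1e-8) on the shared variant.  Upstream association significance is
trusted by default; `--verify` re-tests b1 and b2 within the run and flags
rows that fail.

## Synthetic data generator

`simulate_trio_data` draws Hardy–Weinberg genotypes (dosage ~ Binomial(2, f),
f uniform on the MAF range, monomorphic draws regenerated), then generates
C = b1·G + Γc·Cov + λc·h + ε and T = b3·C + b4·G + Γt·Cov + λt·h + ε with
Gaussian noise.  Defaults: n = 300 samples (a realistic bulk-cohort scale),
MAF ∈ [0.05, 0.5] (common variants only, mirroring standard QC exclusions),
b1 = 1.0, b4 = 0.3, b3 = 0.5 for non-null trios, half the trios null, noise
sd 1.0, two known covariates with effects ~N(0, 0.3), optional hidden factors
loading on both transcripts.  Each study carries a truth table (true b's and
null labels) for end-to-end power/type-I measurement.

What the generator does *not* emulate: linkage disequilibrium between
variants, count-based RNA-seq noise or library-size effects, non-Gaussian
expression tails, relatedness/population structure, and missing genotypes.
Passing tests therefore certify the statistical machinery under its stated
assumptions, not robustness to real-data artifacts; on real cohorts the
usual upstream QC and normalization remain the user's responsibility.

## Problem sizes used in checks

The automated checks run at desk scale: 200 replicates for tail-accuracy
checks (N = 100 permutations each), 300 trios for scheme agreement
(N = 1,000), 100 analytic-tail trios for resolution, 2,000 trios for null
calibration (N = 1,000, n = 120 samples), and 5,000 draws for GPD parameter
recovery.  These sizes give stable Monte-Carlo estimates while keeping the
full run in minutes; all are re-generated from the seed at run time.

## Known limitations

* The GPD shape is restricted to k ≤ 0.95; extremely short-bounded tails are
  approximated at the boundary.
* The AD critical table covers k ∈ [−0.5, 0.9]; fitted shapes outside are
  clamped (very heavy permutation-null tails are rare in this setting).
* The adaptive estimator's p-values are slightly conservative for trios that
  stop very early (small Γ), which is immaterial for screening but means
  adaptive p-values should not be treated as exact below the stopping scale.
* Genotypes must be hard calls; dosage bins for imputed data are not
  supported as permutation strata.
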