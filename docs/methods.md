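# Methods

## Model and estimation

For each gene the expression vector `y` (length n) follows a Gaussian
linear mixed model: fixed-effect terms `X_j β_j` (continuous covariates and
categorical covariates with few levels), independent random intercepts
`Z_k α_k` with one variance `σ²_k` per term, and residual `ε ~ N(0, σ²_ε)`.
Genes are fit independently; only summaries combine genes.

Estimation profiles out both the fixed effects and the residual variance:
with variance ratios `γ_k = σ²_k/σ²_ε` and marginal covariance
`V(γ) = R + Σ_k γ_k Z_k Z_kᵀ` (R = I, or diag(1/w) for weighted fits), the
GLS coefficients and `σ̂²_ε = rᵀV⁻¹r/n` have closed forms, leaving a
profiled log-likelihood in `θ = log γ` alone. That objective is maximised
with L-BFGS-B using the analytic gradient
`∂(−2ℓ)/∂γ_k = tr(V⁻¹Z_kZ_kᵀ) − n·(rᵀV⁻¹Z_kZ_kᵀV⁻¹r)/(rᵀV⁻¹r)` (times
`γ_k` on the log scale). ML is the default; REML replaces n by n−p, adds
`log|XᵀV⁻¹X|`, and is exposed as an option.

Numerical choices:

- Log parameterisation bounds every component at zero; components whose
  share of the total falls below 1e-8 are reported as exactly 0. Boundary
  ("singular") fits are valid outputs, not errors.
- `θ` is bounded in ±25; the objective returns +∞ on a Cholesky failure so
  an overshooting line-search step is rejected rather than crashing.
- The profiled objective can be nearly flat between an interior optimum and
  the zero-variance boundary, and a long first line-search step sometimes
  jumps the basin. The optimizer therefore restarts from variance ratios
  {0.5, 0.05, 5} and keeps the best likelihood, exiting early when a start
  converges to a clean interior optimum. On balanced one-way designs the
  result matches the ANOVA-mean-squares closed form to ~1e-8 relative error.
- Convergence uses the optimizer's relative-reduction criterion (ftol
  1e-14, gtol 1e-10, 500 iterations); non-convergence flags the gene and
  returns the last iterate instead of aborting a genome-wide run.
- Dense n×n linear algebra throughout: the package targets designs up to a
  few thousand samples, where a Cholesky per objective evaluation is
  cheaper than sparse bookkeeping.

## Variance fractions

Fixed-term variances are the post-hoc `var(X_j β̂_j)` with the conventional
n−1 denominator (configurable `ddof`); the intercept contributes nothing.
The total is the plain sum of fixed-term variances, random-term variances
and the residual — cross-covariances between correlated fixed terms are
deliberately not assigned to any term, so the total can differ from
`var(ŷ)` under collinearity. Categorical fixed effects use treatment coding
with the first sorted level as reference; with correlated terms the
coding affects `var(X_j β̂_j)`, which is why the coding is fixed and
deterministic rather than configurable per run.

The OLS/ANOVA comparator refits every term as a fixed effect by least
squares and applies the same post-hoc rule. Its residual variance uses the
ML denominator n (not n−p) so that on a fixed-effects-only model the
comparator and the mixed-model fit produce identical fractions; this makes
the two routes directly comparable and, if anything, slightly flatters the
comparator's known inflation with many-level factors. A rank-deficient
combined design raises an identifiability error — the decomposition does
not exist there, which is precisely the situation (e.g. sex and ancestry
constant within individual) where the mixed model still works.

## Weights

Supplied per-sample weights are precisions by default: residual covariance
`diag(1/w)·σ²_ε`, so high-precision observations get small residual
variance. A `weight_convention="variance"` switch accepts variance-scale
weights instead. Weights are normalised per gene to geometric mean 1; their
overall scale is then absorbed into `σ²_ε`, and constant weights reproduce
the unweighted fit exactly. The residual component entering the fractions
is the parameter `σ̂²_ε` (the residual variance at unit precision).

## Varying-coefficient partitions

`(stratifier|group)` expands into one indicator block per stratifier level
(group-within-level), each with its own variance. Each block's fraction is
reported against a subset-specific total: that block's variance, plus
shared random components and the residual, plus fixed-term contributions
evaluated within the subset. Shared terms and the residual are reported
against the global total (with varying contributions entering as their
sample-size-weighted average). Whether shared components should enter the
subset denominators is genuinely open; this package includes them because
a within-subset observer would see that noise, and records the choice
here. The resulting rows are flagged `sums_to_one=False`. A stratifier
level in which no group level is replicated cannot separate its component
from noise; it is reported as NaN with a `not_estimable` flag, never as 0.

## Synthetic data generator

The generator emulates the structure of multi-factor expression studies:
replicated individuals, factor levels that are invariant properties of
another factor (sex/ancestry per individual — the degenerate-ANOVA
structure), nested factors (library within lab), crossed batch factors,
continuous covariates, subset-specific cross-individual variance, and
optionally heteroskedastic residuals whose true precisions are emitted as
a weight matrix. Per-gene totals are 1, so target fractions are component
variances directly.

Two modes:

- `exact` (default for validation): per-level effects are drawn, then each
  component's contribution is centred, decorrelated from previously built
  components (within the factor's own indicator span, so factor structure
  is preserved) and rescaled so its realized sample variance equals the
  target exactly. The realized decomposition then equals the target
  decomposition, making recovery tests measure estimator error rather than
  generator sampling noise. Decorrelation order is continuous covariates
  first (their direction is rigid), then factors by ascending level count.
- `sampled`: contributions are drawn at their expected variance; realized
  fractions fluctuate as in nature and converge to the targets as level
  counts grow.

What the generator does **not** emulate: count-level sampling, library-size
and normalisation effects, correlated genes, non-Gaussian effect
distributions, outlying samples. Passing recovery tests therefore
demonstrates estimator correctness under the model's own assumptions, not
robustness to real-data pathologies.

Reference validation conditions (chosen as a realistic replicated-individual
study at desk scale): 250 individuals × 2 replicates (n=500), sex (2) and
ancestry (5) invariant per individual, a crossed 7-level lab; generating
fractions 0.55/0.07/0.05/0.00 with residual 0.33; 100 genes. Under these
conditions per-term median absolute recovery error is ≤ 0.02 and the term
ranking is recovered exactly. The overfitting contrast uses n=200 with a
single factor at 0.2 FVE and level counts 5–100; the weighted comparison
uses a mean–variance slope of 1.5 (residual sds spanning ~e^±1.5 across the
expression range), where correct precision weights roughly halve the
fraction RMSE. Smaller unit-test scenarios use the same shapes at reduced
n and gene counts to keep the default test run fast.

With only two replicates per individual the ML cross-individual fraction
shrinks slightly (the median estimate at the reference conditions is
~0.54 against a generating 0.55, and ~0.47 at n=120); this is ordinary
small-sample shrinkage of variance-component ML, not a defect, and it
shrinks as replication grows.

## Genome-wide driver

Per-gene tasks are pure functions of (y, weight row, shared designs);
reduction preserves input gene order, so results are bitwise identical for
any worker count and across repeated runs. Constant genes are pre-filtered
into the flagged set (`constant`) and reported as all-residual; per-gene
numerical failures are caught and flagged, never silently dropped.
Degenerate and non-converged genes are excluded from genome-wide medians.

`binned_curve` relates a per-gene fraction to a binary gene annotation
(e.g. "has a detected cis-eQTL"): genes are sorted by the fraction, a
sliding window (default 200 genes, overlap 100) gives empirical outcome
probabilities, and a logistic regression of the flag on the untransformed
fraction gives the smooth; the genome-wide mean is the reference line. A
logit-transformed x-axis is a plausible alternative; untransformed is the
default and the slope/p-value are exposed so users can refit as they wish.

## Known limitations

- Dense algebra limits practical sample counts to a few thousand.
- No interaction terms, nested random-effect syntax beyond the
  varying-coefficient form, or continuous random slopes.
- No standard errors or tests on fixed effects, and no confidence
  intervals on fractions.
- Weight estimation is upstream (weights are consumed, not estimated), as
  is normalisation and expression-level filtering.
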