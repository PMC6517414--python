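# Methods

## The model

The package analyses aging as the dynamics of a gene regulatory network
poised near an order–disorder bifurcation.  Linearized about the youthful
steady state, expression obeys `dx/dt = K x + noise`, where `K` is the
gene–gene interaction matrix.  Near criticality exactly one eigenvalue of
`K` is small and positive — the network stiffness `α` (1/day) — while every
other mode relaxes at rates `≥ gap`.  Three consequences organise the whole
analysis:

1. **One-factor expression.** Fluctuations are dominated by the critical
   mode: `x_i = x̄_i + b_i z + ξ_i`, with `b` the unit-norm right eigenvector
   (the aging direction) and `z` the mode amplitude, interpretable as
   biological age.  The covariance is rank-one-dominated,
   `⟨δx_i δx_j⟩ ~ b_i b_j e^{αt}`, so PC1 of a clean study aligns with `b`.
2. **Scalar Langevin dynamics.** `dz = α z dt + σ dW`: on average `z` departs
   exponentially from the youthful state at rate `α`.
3. **Mortality.** Death is modelled as the first passage of the deviation
   magnitude `|z|` over a threshold `z_crit`: large excursions of the
   transcriptome from the youthful state, in either direction along the
   critical mode, are incompatible with survival.  Writing
   `z(t) = e^{αt} Y_t` with `Y_t = z0 + ∫ σ e^{-αs} dW_s`, the integrated
   noise `Y_t` converges, so a path with terminal value `Y` dies near
   `t(Y) = ln(z_crit/|Y|)/α`.  Because `|Y|` has positive density at 0⁺, the
   survival fraction decays as `e^{-αt}` at late times and the hazard
   **plateaus exactly at α**, while near the mean lifespan the hazard rises
   approximately exponentially — the Gompertz regime `M(t) ≈ M0 e^{αt}`.
   The magnitude threshold is essential: a one-sided threshold (`z ≥ z_crit`
   only) leaves the paths whose integrated noise went negative immortal, the
   late-life hazard *decays*, and no plateau at `α` exists.  We verified both
   statements by simulation and adopted the magnitude mechanism; the
   analytic plateau constant is otherwise not derived here, only
   simulation-verified (plateau/α ≈ 0.93–1.08 across a 10× range of α at
   n = 2·10⁴ animals per cohort).

Temporal scaling follows from self-similarity: cohorts differing only in `α`
are exact time-rescalings of one another, so survival curves and aging
trajectories superimpose when age is divided by the cohort mean lifespan
`t̄` (`α t̄` is a dimensionless constant of the family).

## Survival statistics

- Kaplan–Meier and Nelson–Aalen are implemented directly (product-limit and
  `m(t) = Σ d_i/n_i` with Poisson variance `Σ d_i/n_i²`); deaths precede
  censorings at tied times; `lifelines` serves as an independent cross-check
  in the tests and provides the Mantel–Cox log-rank statistic.
- **Gompertz fit**: nonlinear least squares of the Nelson–Aalen cumulative
  hazard against `(M0/α)(e^{αt} − 1)` in log-parameters (both rates
  positive; `expm1` keeps the α→0 exponential limit exact).  Only event
  times with Kaplan–Meier survival inside the window `[0.9, 0.25]` enter the
  fit — the stiffness coincides with the Gompertz exponent only near the
  mean lifespan.  The window is configurable; fitting `m(t)` rather than
  `S(t)` is equivalent up to weighting and is the convention here.
- **Plateau**: ordinary least squares of `m(t)` on `t` over the event times
  after 80 % of deaths (configurable tail fraction), slope = `M(t ≫ t̄)`
  with its OLS standard error.  Diagnostics compare the tail slope with the
  mid-life hazard (same regression over survival `[0.65, 0.35]`); strictly
  Gompertz data trip the `exceeds_midlife` flag (ratio > 2 and > 2 SE).
  With ~2·10⁴ deaths the constant-hazard and first-passage checks resolve
  the plateau to a few percent; at a few thousand deaths the tail regression
  is noisy (the exponential-limit bound `α̂ ≤ 0.02/t̄`, for example, needs
  ~2·10⁴ deaths to hold reliably).
- **Collapse statistic**: survival curves are step-interpolated onto a
  common grid of `t/t̄ ∈ [0, 2]` (401 points) and compared by the maximum
  over curve pairs of the sup-distance.  At n = 2000 per cohort the
  sampling floor of this statistic is ≈ 0.03–0.045; exact time-scalings
  land well under 0.06 while 10-fold `M0` differences at equal `α` exceed
  0.1.
- Lifespan summaries average uncensored deaths (lost animals are censored
  and excluded), matching the convention of the published tables; the
  Kaplan–Meier restricted mean is reported alongside and coincides when no
  censoring is present.  Printed extensions follow the tables' rounding:
  one decimal below 100 %, nearest ten above.

## The synthetic study conditions

The generator emulates a compilation of small public aging studies:

| parameter | default | meaning |
|---|---|---|
| `G` | 500 | genes |
| support fraction | 0.1 | genes with nonzero aging loading |
| loadings `b` | ±1/√k, random signs | equal magnitude on the support, unit norm |
| `x̄` | N(6, 1.5²), clipped ≥ 1 | baseline log-abundance |
| `resid_sd` | 0.03 | per-sample residual ξ |
| `c = α t̄` | ln 10 ≈ 2.303 | shared time-scale constant |
| `z0` | 0.1 | youthful order parameter (threshold = 1) |
| z noise scale | 0.025 | ⇒ ~25 % relative spread of z at `t = t̄` |
| datasets | 20, 8–16 samples each | small independent studies |
| lifespans | log-uniform 17–160 d | the ~10× range of the cohorts |
| ages sampled | window of width 0.9 in `t/t̄ ∈ [0.05, 1.05]` | per dataset |
| batch | `x → s_d x + o_d`, `s_d ∈ [0.8, 1.25]`, `o_d ~ N(0, 0.03²)` per gene | affine per dataset |

Choices and rationale.  Cohort stiffness is `α = c/t̄` with one shared `c`,
which *enforces* the scaling hypothesis: the law of `z` at rescaled age
`u = t/t̄` is cohort-independent, `z(u) ~ N(z0 e^{cu}, 0.025²(e^{2cu}−1))`.
Equal-magnitude loadings give every support gene the same effect size, so
sensitivity against the truth channel is a meaningful quantity (with
Gaussian loadings a sizeable fraction of "true" genes is undetectable in
principle).  The affine batch model is the simplest that makes dataset
labels dominate total variance (η² ≈ 0.44 by dataset vs ≈ 0.04 by age at
the defaults) while leaving the per-gene aging signal recoverable by
meta-analysis.  Residual and batch scales were calibrated once, by
simulation, to sit in the regime the analysis assumes — batch-dominated
pooled variance, per-gene associations detectable only by pooling datasets.
A negative-binomial count mode (dispersion 0.1 on means `e^x`) exercises
the zero-filter/upper-quartile/RPKM path with integer data; the continuous
mode is the default for model-recovery work.

What the generator does **not** emulate: correlated residuals and gene–gene
covariance beyond the single factor, platform-specific probe effects,
nonlinear saturation of expression at late ages, heterogeneous rates of
aging within a cohort, and lifespan-dependent sampling loss.  Passing
recovery tests therefore certify the estimators and the pipeline logic
under the stated statistical structure, not biological discovery on real
compilations.

## Normalization

Zero-count filter (a gene is dropped if any sample has a zero count) →
upper-quartile scaling (per-sample 75th percentile of nonzero counts,
referenced to the geometric mean of those percentiles — a symmetric,
scale-free choice) → RPKM (`count / (length/10³ · library/10⁶)`).
Cross-platform collections use the YuGene cumulative-proportion transform:
per sample, genes are sorted by decreasing value and scored
`1 − cumsum/total` (inclusive cumulative sum); tied values share their
block's mean score.  The scores lie in `[0, 1)`, preserve ranks, and are
invariant to per-sample scaling — which is precisely what removes the
dominant batch scale here.  The transform is deliberately not idempotent
(it reshapes the value distribution); tests assert this rather than assume
it.

## Signature and clock

Per-gene association is a two-sided Pearson (optionally Spearman) test of
expression against age rescaled by lifespan, vectorized across genes.  The
ensemble draws `B = 200` resamples of 50 % of the *datasets* without
replacement, marks genes significant at `0.005/G` (Bonferroni; at the scale
of a 4861-gene universe this is ~1.03·10⁻⁶ per gene), and keeps genes
significant in ≥ 50 % of resamples whose slope sign agrees in ≥ 70 % of
their significant resamples (a signature gene needs a direction; the 0.7
consistency cut is our choice).  Dataset-level resampling is what buys
batch robustness: an association driven by a few datasets does not survive
resamples excluding them, whereas a single pooled split admits such false
positives.

The clock is a lasso of rescaled age on signature-gene expression.
Cross-validation is grouped by dataset (whole datasets held out), matching
the way such clocks are validated on unseen experiments; the penalty
follows the one-standard-error rule (sparsest model within one SE of the
minimum CV error), the standard choice when the support matters — with the
error-minimum rule the chosen model carries several spurious genes and
exact support recovery of a lone informative gene drops from ~98 % to
~25 %.  Reference levels `x̄` are training-collection gene means; the
prediction `z = intercept + Σ a_i (x_i − x̄_i)` is affine in expression and
dimensionless (≈ 0 at the adult molt, ≈ 1 at the mean lifespan).  The
weights themselves are not identifiable — the support genes are strongly
collinear, so the lasso concentrates weight on an arbitrary subset (any
vector orthogonal to `b` can be added with little effect on predictions).
Accordingly the package asserts sign-consistency of selected weights and
accuracy of the *projection* (held-out correlation with the true `z`
≈ 0.9 at the defaults), never weight-vector recovery.

A note on PC1: on a single clean, low-noise study PC1 is an excellent
biomarker, and the meta-trained clock has no advantage.  The familiar
failure of single-study PCA appears in the high-dimensional noise regime
(per-gene noise comparable to per-gene signal at n ≈ 12 samples, G = 500),
where PCA loses consistency; the paired comparison test is run there.

## Problem sizes and numerics

Default experiment sizes — 8 cohorts × 2·10⁴ first-passage paths
(Euler–Maruyama, `dt = 0.01/α`, horizon 3.2 deterministic lifespans),
20-dataset collections of ~12 samples × 500 genes, `B = 200` resamples,
25-point penalty grids — were chosen so the full pipeline runs in seconds
to minutes on one CPU; all statistics quoted above were measured at these
sizes.  The network integrator enforces the explicit-scheme bound
`dt · gap ≤ 0.5`; random network bases are redrawn (bounded retries) until
the condition number is ≤ 100.  One integer seed drives everything through
`numpy` `SeedSequence` spawn keys, one independent stream per operation;
fixed seed and path count give bitwise-reproducible cohorts, studies,
models and reports.

## Limitations

- The `z → mortality` link is a modelling choice (magnitude first passage
  over a fixed threshold); the package treats it as the definition of the
  death mechanism, not an inference from data.
- No inference of `K` from data; the network module only verifies the
  reduction from `G` dimensions to the scalar mode.
- The plateau estimator needs deaths observed out to ~2–3 `t̄`; truncated
  follow-up biases the tail slope toward the mid-life hazard.
- No frailty/heterogeneity mortality models and no parametric plateau
  laws; the tail regression is the only late-life estimator, as specified
  for this analysis.
- Whether a real clock should predict rescaled or raw age is a substantive
  choice; this package trains on rescaled age throughout (one model across
  a 10× lifespan range), and raw-age training would need per-strain
  recalibration.
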