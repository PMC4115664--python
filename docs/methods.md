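# Methods

This note records the statistical model behind each stage of the audit,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Study-level model

A study is a two-condition experiment summarised by Cohen's
*d* = (x̄₁ − x̄₂)/s_pooled (positive = the focal condition performs worse)
and the per-condition counts (n₁, n₂). The sampling variance uses the
standard large-sample form

v = (n₁ + n₂)/(n₁ n₂) + d²/(2(n₁ + n₂)),

the default in meta-analysis practice when only (d, n₁, n₂) are coded.
Per-study significance is a normal z-test, z = d/√v, two-sided, with the
*strict* inequality p < α defining "significant" (α = 0.05 throughout
unless configured). Using one criterion everywhere keeps the significance
counts, the power model and the funnel contours mutually consistent. A
Hedges small-sample correction (J ≈ 1 − 3/(4df − 1)) is available behind a
flag but off by default: coded effect sizes are taken as coded.

Effects are deliberately *not* recomputed from raw means or test
statistics; the package starts where an effect-size coding effort ends.

## Pooling and heterogeneity

Fixed-effect pooling weights by 1/vᵢ; DerSimonian–Laird random-effects
adds the method-of-moments τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) to every
variance. DL was chosen over REML because it is the de-facto standard for
this literature's era and is what reference implementations (metafor's
`method="DL"`) default to historically; the package's output matches
metafor to ~10 significant digits on the frozen fixtures. Confidence
intervals are z-based (θ ± 1.96·se), matching conventional meta-analytic
output; t-based intervals would be wider at small k.

When τ² = 0 the random-effects fit coincides with the fixed-effect fit
exactly; the analysis layer always computes it, and only the formatted
tables mask it as "NA" (the convention used in published summary tables
for homogeneous subsamples).

Rosenberg's weighted failsafe-N asks how many null studies of mean weight
w̄ must be added before the fixed-effect combined z drops below the α
critical value; it is included because the audited literature's original
synthesis leaned on it, not because it is recommended — the number answers
a question ("could unpublished nulls cancel the signal?") that the other
methods answer better.

## Excess significance

The test treats the set's mean power as the probability that any one study
is significant and compares the observed significant count O with
Binomial(k, mean power), one-tailed (P(X ≥ O)). Power for an assumed
effect δ uses the null-variance standard error se₀ = √(1/n₁ + 1/n₂):

power = Φ(δ/se₀ − z_{1−α/2}) + Φ(−δ/se₀ − z_{1−α/2}),

so that power(0) = α exactly — the power model then agrees with the
significance criterion about the null. The cost is a ~0.01–0.02 upward
shift relative to a simulated t-test power at typical n; audit-scale
conclusions are insensitive to it. Three bases for δ are provided: the
fixed-effect estimate, the random-effects estimate, and each study's own
coded d ("individual"). The single-mean-power binomial is the test as
originally specified; because power varies across studies the exact
reference distribution is Poisson–binomial, provided behind a flag for
sensitivity analysis (it is the more conservative of the two in the cases
that matter).

Calibration: on uncensored simulated literatures with a correctly
specified effect the test's rejection rate sits at or slightly below the
nominal level (binomial discreteness plus the null-variance power model
both push conservative); it never over-rejects. Under censoring it is
extremely sensitive — at π = 0.05 it flags essentially 100% of simulated
literatures.

## Trim-and-fill

The L0 and R0 rank estimators of the missing-study count follow Duval and
Tweedie: deviations cᵢ = dᵢ − θ are ranked by |cᵢ| (average ranks on
ties), L0 = round((4S − k(k+1))/(2k−1)) with S the positive-deviation
rank-sum, R0 = (run of consecutive top ranks that are all positive) − 1,
both floored at 0. The loop trims the estimated number of most-extreme
same-side studies, re-pools (fixed-effect inside the loop by default),
re-estimates, and stops when the count stabilises (cap 50 iterations, a
warning flag on non-convergence). Filled studies are exact mirrors
(d* = 2θ − d, variance inherited unchanged) and both models are re-pooled
on the augmented sample, with τ² re-estimated on it. The side carrying
the surplus defaults to auto-detection by the sign of Kendall's τ(d, se).

L0 with fixed-effect inner pooling is the default because it is the
reference implementations' default and the better-behaved estimator in the
original simulation studies. Output matches metafor's `trimfill()` exactly
on the frozen fixtures (both estimators, both pooling models).

One caveat discovered in validation and worth knowing: the "fixed-point"
intuition — running trim-and-fill on an already-filled sample should
impute nothing — holds almost always but not universally. L0's integer
rounding can sit just above ½ on the augmented funnel and emit one
residual imputation (observed in ~1/40 simulated censored samples;
metafor reproduces the same residual on the same sample). It is a property
of the estimator, not of the implementation.

## PET-PEESE

Both models are weighted least squares with weights 1/seᵢ², solved in
closed form, with coefficient covariance scaled by the multiplicative
dispersion σ̂² = Σwᵢeᵢ²/(k − 2) and t-inference on k − 2 df — the
conventional Egger-regression treatment, and the one that reproduces
published coefficient tables. PET's slope is algebraically the classical
Egger asymmetry statistic (same t, same p); asymmetry is declared at
p < 0.10, a deliberately liberal conventional cutoff, while the PET-PEESE
*branch* is tested two-sided at 0.05 (equivalently: does PET's 95% CI
exclude zero). A one-tailed branch variant (requiring a positive PET
intercept) is available behind a flag.

Behaviour under the generator's censoring model, measured rather than
assumed: at δ = 0 with strong selection PET's intercept is the least
biased of the estimators but lands slightly *below* zero (mean ≈ −0.11 at
π = 0.05, k = 198). The mechanism is structural: v depends on d through
the d²/(2N) term, so the predictor (se) is an increasing function of the
outcome on the positive side, steepening the fitted slope and pulling the
intercept down. With a genuinely non-zero effect PET over-corrects more
substantially while PEESE stays close to truth — the crossover that
motivates the conditional rule.

## Synthetic literatures

The generator emulates the audited field's study conditions:

- **Outcomes**: per-subject unit-variance normals, mean shifted by the
  true δ in the focal condition; d computed with the pooled SD. On the
  undistorted path the generator draws d's sufficient statistics directly
  (normal mean difference and an independent scaled-χ² pooled variance),
  which is distributionally identical and orders of magnitude faster; the
  two paths are tested against each other.
- **Sample sizes**: per-condition n from a discretized lognormal with
  σ = 0.5 and μ = ln 27 − σ²/2, i.e. mean exactly 27 before rounding and
  quartiles ≈ (17, 33) — calibrated to the depletion literature's reported
  mean 27 and IQR 17–31. The upper quartile overshoots by ~2 because a
  two-parameter lognormal cannot hit mean and both quartiles at once; the
  mean and lower quartile were prioritised since pooling weights and power
  are most sensitive to the small-n mass. Floor at n = 5. A resampling mode
  draws (n₁, n₂) pairs from a supplied study table instead.
- **Censoring**: one-sided. A study is published with probability 1 iff it
  is significant *in the expected direction*; every other study —
  non-significant or significant the wrong way — is published with
  probability π (default 0.05, heavy selection). One-sidedness matters: a
  direction-blind rule would leave the δ = 0 funnel symmetric and produce
  no bias at all, contradicting the funnel-asymmetry narrative the model
  exists to emulate.
- **Distortions**: optional stopping (test at n_start, top up by n_step
  until significant or n_max; the reported d uses the data at stopping)
  and multiple outcomes (m equicorrelated outcomes, pairwise ρ via a
  shared-component construction; the max-|z| outcome is reported). Each
  published study carries a flag marking whether the practice converted a
  non-significant first look/first outcome into a significant report.
- **Bookkeeping**: attempted and suppressed counts, the true δ, and the
  seed; a literature is byte-for-byte reproducible from its config.

What the generator does *not* emulate: between-study heterogeneity in the
true effect (all studies share one δ; estimators' behaviour under genuine
τ² > 0 is therefore out of the validated envelope), correlated effect
sizes from multi-effect papers, moderator structure behind subgroup
labels, and any content-specific features of the two-task experimental
paradigm. Passing simulation tests demonstrates estimator behaviour under
pure selection on significance, not under every mechanism that can bend a
real funnel plot.

## Numerical conventions and degenerate inputs

- Normal critical value 1.959963984540054 (Φ⁻¹(0.975)) everywhere a 95%
  z-interval appears; t quantiles on k − 2 df in the regressions.
- k = 1: heterogeneity is degenerate (Q = 0, I² = 0, τ² = 0, flagged);
  random-effects pooling requires k ≥ 2; trim-and-fill and the regressions
  require k ≥ 3; WLS additionally requires a non-constant predictor
  (all-equal standard errors are a collinearity error).
- Trimming is capped at k − 2 so the inner pool always has ≥ 2 studies.
- Subsamples with k < 10 carry an explicit caution flag: funnel-based
  methods are unreliable there, and the battery says so rather than
  declining to compute.
- Table formatting rounds estimates to two decimals and switches p-values
  below 0.001 to scientific notation; the underlying report object keeps
  full precision, and the emitted tables parse back to the printed
  precision.
- The analysis path contains no randomness: identical input and config
  produce byte-identical reports. All simulation randomness flows from a
  single integer seed through one numpy Generator.

## Problem sizes used in the validation suite

Simulation-backed tests use literatures of 40–200 published studies and
25–500 replicates per property (500 for the headline censored-null and
parameter-recovery checks, matching the precision at which the measured
biases are scientifically interpretable); distributional equivalence
checks use 6,000 draws, and calibration of the excess-significance test
uses 5,000 simulated literatures. The whole suite, including those
simulations, runs in a few minutes on one CPU.
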