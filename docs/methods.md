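# Methods

## Model and assumptions

The design assumes a single continuous biomarker whose population
distribution is well characterised, so that each raw measurement can be
mapped to its quantile B and the population quantiles are uniform on
[0, 1].  Response is binary and its probability is assumed smooth and
monotone **increasing** in the biomarker (a negatively associated biomarker
must be sign-flipped by the caller before entry).  On the quantile scale
the point response rate is logistic, π(B) = expit(δ₀ + δ₁B), and all design
reasoning is in terms of the subset response rate

Π(B) = E[π(U) | U ≥ B] = ln[(1 + e^{δ₀+δ₁}) / (1 + e^{δ₀+δ₁B})] / (δ₁(1 − B)),

the closed form following because the integral of the logistic function is
the softplus.  A completed trial always analyses exactly S = S₁ + S₂
subjects with the pooled one-sided binomial exact test against the
reference rate ρ; significance uses the convention p ≤ α, applied
consistently in the test itself and in the pre-computed required-response
count X_H.  Because recruitment is restricted to B ≥ max(t₁, t₂) and Π is
monotone, a significant pooled test implies a qualifying subpopulation
exists, so the pointwise test is a valid test of the composite null.

## Tunable parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `s1`, `s2` | stage sample sizes (subjects) | — | equal stages are a good generic choice |
| `t1` | stage-1 recruitment threshold (quantile) | — | choose near the best prior guess of the qualifying threshold |
| `rho` | reference response rate | — | clinical significance, e.g. historical control rate |
| `alpha` | one-sided significance level | 0.05 | |
| `target_power` | interim target predicted power 1 − β | 0.8 | |
| `gamma` | AD2 fallback bound | — | pinned to `target_power` for AD1 and 0 for AD3 |
| `beta_fd` | FD1 futility parameter | 0.8 | stop when predictive success probability < 1 − β_FD = 0.2 |
| `t2_grid` | candidate stage-2 thresholds | 0, 0.05, …, 0.95 | 20 values; grid points below t₁ extrapolate the stage-1 fit |
| `n_draw` | MVN coefficient draws | 1000 | shared across all grid points of one interim |

## Interim numerics

* **Coefficient uncertainty.**  The stage-1 logistic fit uses maximum
  likelihood (statsmodels `Logit`); the covariance is the inverse observed
  Fisher information.  Draws are bivariate normal around the MLE.  A
  covariance that is not positive semi-definite (possible with
  near-separated data) is repaired by clipping negative eigenvalues at
  zero, with a logged warning.
* **Beta fit.**  The Π̃(t*) draws are clamped to [1e-9, 1 − 1e-9] (MVN
  draws can produce negative slopes and hence extreme rates) and summarised
  by method-of-moments Beta(a, b): a = m(m(1 − m)/v − 1), b = a(1 − m)/m.
  Moments are deterministic and fast; the moment variance is additionally
  capped just below m(1 − m) so a, b stay positive.  A draw set with
  variance below 1e-12 bypasses the beta fit and uses the plain
  Binomial(S₂, m) tail (the beta is undefined at zero spread).
* **Boundary counts.**  A remaining requirement X_H,2 ≤ 0 yields predicted
  power 1, X_H,2 > S₂ yields 0; both are returned, not raised.  In the FD1
  rule the boundary posteriors Beta(0, S₁) and Beta(S₁, 0) are taken as
  their point-mass limits (predictive success probability 0 and 1).  The
  FD1 comparison with the futility bound is strictly `<`.
* **Degenerate stage-1 fits.**  When no finite MLE exists (all responses
  identical, or separated data) the adaptive rules use the analytic limits:
  zero responses → predicted power 0 everywhere → stop; otherwise →
  continue at the smallest grid threshold (the data are consistent with the
  most optimistic curve, predicted power 1 in the limit).  These events are
  flagged in the interim record.
* **Subset-rate evaluation.**  ln(1 + e^z) is computed with `logaddexp`
  (stable past |z| = 700, which extreme MVN draws do reach).  For
  |δ₁| < 1e-8 the closed form divides by ~0 and is replaced by its analytic
  flat-curve limit expit(δ₀); at B = 1 the limit π(1) is returned.  The two
  branches agree to < 1e-8 at the switch point.

## Calibration and quantile conventions

* `calibrate_intercept` solves Π(anchor) = target for δ₀ by Brent's method
  on [−50, 50] (Π is strictly increasing in δ₀, so the root is unique);
  tolerance 1e-12.  Null scenarios with two constraints (Π(0) and a margin
  value at B = 0.95) solve for the slope by an outer root-find with the
  intercept re-calibrated at each step, slope bracket (0, 40].
* The empirical quantile transform uses quantile = (#reference ≤ v)/n (ties
  take their maximum rank): the reference maximum maps to 1, values below
  the reference minimum to 0.  Any monotone convention would do; this one
  is simple and exactly invertible on reference points, and the raw-scale
  threshold report is the smallest reference value whose quantile reaches
  T̂ (nearest order statistic, no interpolation).

## Threshold estimation

T̂ is the argmin of |Π̂(B) − ρ| over the grid 0, 0.001, …, 0.999 — fine
enough to resolve estimates quoted to two decimals.  Ties take the smaller
B, consistent with preferring the largest qualifying subpopulation.
Intervals are the empirical quantiles of per-draw argmins T̃ under MVN
coefficient resampling (default coverage 0.75, a free parameter).  An
alternative construction — inverting the distribution of |Π̃(B) − ρ| at
fixed B — would be possible but is not implemented; the per-draw-argmin
reading is the simpler and more direct resampling analogue.  For trials
stopped at the interim, T̂ reuses the stage-1 fit, so an estimate is
reported for every trial with a non-degenerate fit.

## Simulation harness

Synthetic trials draw stage-i quantiles uniformly on [tᵢ, 1] and responses
as Bernoulli(π(B)).  Expected screening effort is accounted analytically as
n/(1 − t) per stage rather than by simulating screen failures — this
matches the design arithmetic (100 screens for a stopped study and 200 for
a completed one at t = 0.5 with 50-subject stages) and removes needless
Monte-Carlo noise.  One master generator spawns independent substreams for
stage-1 data, coefficient draws, stage-2 data and estimation draws, so the
whole pipeline is bit-reproducible under a fixed seed and changing
`n_draw` does not perturb recruitment.  Only the stage 2 actually selected
is generated; its distribution is identical to generating all candidate
stage-2 datasets up front and picking one, for every aggregate reported
here.

The generator emulates the design's idealised conditions: perfectly known
biomarker distribution (exact uniform quantiles), exchangeable subjects,
instantaneous outcomes, no dropout and no accrual-time or screening-cost
structure beyond the 1/(1 − t) factor.  Passing tests therefore
demonstrate the statistical machinery under the stated model, not
robustness to model misspecification, assay drift or censoring — real
applications should add scenario sweeps of their own.

For constant response rates and fixed-threshold designs, operating
characteristics are computed exactly by enumerating the stage-1 count
X₁ ~ Binomial(S₁, π): the stopping rule is deterministic in X₁ and the
stage-2 remainder is an independent binomial tail.  This enumeration serves
as the oracle for the Monte-Carlo path in the tests.

## Scenario constants

The built-in biomarker-effect scenario table (`TABLE2_ROWS`) anchors each
curve either at the true threshold (Π(T) = ρ = 0.4) or at the
hypothesis-testing threshold (Π(T_H) = R_H = 0.49), with slopes 3, 6 and 9.
Null scenarios are specified by Π(0) together with Π(0.95) = 0.399,
marginally below ρ = 0.4 (the margin is configurable; results are
insensitive to its exact value).  The one steep scenario whose published
threshold pair is internally inconsistent at printed precision is anchored
at its true threshold, the choice that matches its published subset-rate
summaries.

## Problem sizes used by the test suite

Monte-Carlo tests compare proportions within k standard errors
√(p(1 − p)/n) at the replication actually run: the operating-
characteristic checks use 1000 iterations (k = 3), the exact-vs-simulated
cross-checks 4000 (k = 4), the null-conservatism sweep 400 iterations per
design variant and scenario (k = 3, as a one-sided bound on top of
α = 0.05), and the threshold-bias study 1000 trials.  The acceptance
script runs 5000 iterations per stochastic quantity, with the FD1
stopping rate computed exactly.  These sizes keep the full suite to a few
minutes while leaving the Monte-Carlo tolerances meaningful.

## Known limitations

* Binary outcomes only; no control arm; a single interim analysis; the
  stage-2 sample size is fixed in advance.
* The logistic link is assumed, not selected; heavier-tailed
  biomarker-response relationships are not distinguishable at these sample
  sizes and are not modelled.
* The beta moment fit is an approximation to the posterior of Π(t*); it is
  typically close to MCMC-based alternatives but can misrepresent very
  skewed draw sets at extreme thresholds.
* Type-I error is bounded by α but not controlled at it — the design is
  conservative (interim stopping removes part of the null rejection mass),
  so α could in principle be raised; no automatic adjustment is provided.
* The threshold interval is a resampling interval, not a calibrated
  confidence procedure; its coverage is a user choice (default 75 %).
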