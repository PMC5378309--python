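# cbatt — continuous biomarker-adaptive threshold trial design

`cbatt` implements a single-arm, two-stage adaptive enrichment design for
early-phase trials of a treatment with a binary outcome (response /
non-response) and a continuous predictive biomarker whose cut-off for
"biomarker positive" is not known in advance.  It is aimed at trial
statisticians who want to (a) test whether *some* biomarker-defined
subpopulation has a response rate above a clinical reference rate, (b)
estimate the biomarker threshold that defines that subpopulation, and (c)
study the operating characteristics of such a design by simulation before
running it.

## The design

Biomarker values are transformed to their empirical quantiles **B** in a
reference population, so B ~ Unif[0, 1].  Response follows a logistic curve
on the quantile scale,

    π(B) = expit(δ₀ + δ₁ B),

and the quantity of interest is the **subset response rate** — the mean
response rate among subjects with biomarker quantile ≥ B:

    Π(B) = ln[ (1 + e^{δ₀+δ₁}) / (1 + e^{δ₀+δ₁B}) ] / (δ₁ (1 − B)).

The hypotheses are H₀: Π(T*) ≤ ρ for every threshold T*, against
Hₐ: Π(T*) > ρ for some T*, where ρ is a pre-specified reference ("null")
response rate.  With total sample size S = S₁ + S₂ fixed, the minimum
number of responses X_H for a significant one-sided binomial exact test at
level α is known before the study starts.

* **Stage 1** recruits S₁ subjects with B ≥ t₁.
* **Interim**: a logistic model is fitted to stage-1 data; 1000 coefficient
  pairs are drawn from MVN(MLE, inverse observed information); for each
  candidate stage-2 threshold t* the draws of Π̃(t*) are summarised by a
  moment-fitted Beta(a, b); the **predicted power** is the beta-binomial
  tail P(X ≥ X_H − X_ob,1 | X ~ BetaBinomial(S₂, a, b)).  The adaptive rule
  (AD1) continues at the smallest t* whose predicted power reaches the
  target 1 − β, and otherwise stops for futility (variants AD2/AD3 relax
  the stopping rule; FD1/FD2 are fixed-threshold comparators, FD1 with a
  beta-binomial futility rule on the raw stage-1 count).
* **Stage 2** recruits S₂ subjects with B ≥ t₂.
* **Final analysis**: binomial exact test of the pooled response count
  against ρ, and estimation of the true threshold
  T̂ = argmin_B |Π̂(B) − ρ| with resampling intervals.

## Worked example

Reference design (S₁ = S₂ = 50, t₁ = 0.5, ρ = 0.4, α = 0.05, target power
0.8) under a scenario with log odds ratio δ₁ = 6 calibrated so that the
true threshold is T = 0.5 (i.e. Π(0.5) = 0.4):

```python
import numpy as np
from cbatt import DesignSpec, scenario_from_table_row, simulate_oc, subset_rate

design = DesignSpec(s1=50, s2=50, t1=0.5, rho=0.4, alpha=0.05, variant="AD1")
scenario = scenario_from_table_row(6.0, "T", 0.5, 0.40)
print(f"required responses X_H = {design.x_h} of S = {design.s}  (R_H = {design.r_h:.2f})")
print(f"Pi(0) = {subset_rate(scenario.curve, 0.0):.3f}, "
      f"Pi(0.5) = {subset_rate(scenario.curve, 0.5):.3f}, "
      f"Pi(0.95) = {subset_rate(scenario.curve, 0.95):.3f}")
oc = simulate_oc(design, scenario, 1000, np.random.default_rng(7))
print(f"overall power            {oc.prop_significant_overall:.3f}")
print(f"power (completed only)   {oc.prop_significant_completed:.3f}")
print(f"stopping rate            {oc.stopping_rate:.3f}")
print(f"median chosen t2         {oc.median_t2:.2f}")
print(f"median bias of T-hat     {oc.median_bias:+.3f}")
print(f"mean subjects screened   {oc.mean_screened:.0f}")
```

prints

```
required responses X_H = 49 of S = 100  (R_H = 0.49)
Pi(0) = 0.220, Pi(0.5) = 0.400, Pi(0.95) = 0.705
overall power            0.362
power (completed only)   0.690
stopping rate            0.475
median chosen t2         0.80
median bias of T-hat     +0.021
mean subjects screened   275
```

Reading this: 49/100 pooled responses are needed for significance; under
this scenario roughly half of the trials stop for futility at the interim;
those that continue usually raise the recruitment threshold (median
t₂ = 0.8, versus the initial 0.5) and about 69 % of them reach a
significant final test; the threshold estimate is close to unbiased; the
adaptive enrichment costs ~275 expected biomarker screens per trial.

A command-line layer mirrors the library: `cbatt simulate`,
`cbatt oc-table`, `cbatt interim`, `cbatt final` and `cbatt apply`
(sequential recruitment on a subject-level CSV with columns
`subject_id,biomarker,response` plus a reference biomarker sample).  See
`cbatt --help`.

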