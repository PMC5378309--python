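"""Single-trial execution: recruitment, interim decision, final analysis.

A trial under this design runs as follows.  Stage 1 recruits ``s1`` subjects
with biomarker quantiles above ``t1`` (quantiles uniform on [t1, 1] when the
population quantiles are uniform on [0, 1]); responses are Bernoulli at the
scenario's point response rate.  The interim applies one of the adaptive or
fixed rules (see :mod:`cbatt.interim`).  If the trial continues, stage 2
recruits ``s2`` subjects above the chosen threshold (fixed designs reuse
``t1``), and the pooled response count is tested against the reference rate
with the binomial exact test.  The true-threshold estimate is computed from
the pooled fit, or from the stage-1 fit when the trial stopped early.

Expected screening effort is accounted analytically: recruiting n subjects
above quantile t requires on average n / (1 - t) biomarker screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import analysis, interim
from .model import LogisticCurve, Scenario, response_rate

__all__ = ["DesignSpec", "TrialResult", "default_t2_grid", "generate_stage", "run_trial"]

VARIANTS = interim.ADAPTIVE_VARIANTS + interim.FIXED_VARIANTS


def default_t2_grid() -> np.ndarray:
    """The 20 candidate stage-2 thresholds 0, 0.05, ..., 0.95."""
    return np.round(np.arange(20) * 0.05, 2)


@dataclass(frozen=True)
class DesignSpec:
    """All fixed parameters of one trial design.

    Parameters
    ----------
    s1, s2 : int
        Stage sample sizes (total S = s1 + s2 subjects are always analysed
        in a completed trial).
    t1 : float
        Stage-1 recruitment threshold on the quantile scale.
    rho : float
        Reference ('null') response rate tested against.
    alpha : float
        One-sided significance level of the final exact test.
    target_power : float
        Target predicted power 1 - beta used by the adaptive rules.
    gamma : float, optional
        AD2 fallback bound; forced to ``target_power`` for AD1 and 0 for AD3.
    beta_fd : float
        FD1 futility parameter: stop when the predictive probability of
        success is below 1 - beta_fd (default beta_fd = 0.8, bound 0.2).
    t2_grid : tuple of float
        Candidate stage-2 thresholds, strictly increasing within [0, 1).
    variant : str
        One of AD1, AD2, AD3, FD1, FD2.
    n_draw : int
        Number of MVN coefficient draws at the interim (and for threshold
        intervals).
    seed : int, optional
        Convenience seed used by the CLI entry points.
    """

    s1: int
    s2: int
    t1: float
    rho: float
    alpha: float = 0.05
    target_power: float = 0.8
    gamma: Optional[float] = None
    beta_fd: float = 0.8
    t2_grid: tuple = field(default_factory=lambda: tuple(default_t2_grid()))
    variant: str = "AD1"
    n_draw: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.s1 < 1 or self.s2 < 1:
            raise ValueError("stage sample sizes must be >= 1")
        if not 0.0 <= self.t1 < 1.0:
            raise ValueError("t1 must lie in [0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown design variant {self.variant!r}")
        grid = np.asarray(self.t2_grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("t2_grid must be non-empty and strictly increasing")
        if grid.min() < 0 or grid.max() >= 1:
            raise ValueError("t2_grid values must lie in [0, 1)")
        object.__setattr__(self, "t2_grid", tuple(float(g) for g in grid))
        # the AD1/AD3 special cases pin gamma; AD2 must state it
        if self.variant == "AD1":
            if self.gamma is not None and self.gamma != self.target_power:
                raise ValueError("AD1 requires gamma == target_power")
            object.__setattr__(self, "gamma", self.target_power)
        elif self.variant == "AD3":
            if self.gamma is not None and self.gamma != 0.0:
                raise ValueError("AD3 requires gamma == 0")
            object.__setattr__(self, "gamma", 0.0)
        elif self.variant == "AD2" and self.gamma is None:
            raise ValueError("AD2 requires an explicit gamma")

    @property
    def s(self) -> int:
        return self.s1 + self.s2

    @property
    def x_h(self) -> int:
        """Responses required for significance, fixed before the study."""
        return analysis.required_responses(self.s, self.rho, self.alpha)

    @property
    def r_h(self) -> float:
        """Required response rate R_H = X_H / S."""
        return self.x_h / self.s

    def with_variant(self, variant: str, gamma: Optional[float] = None) -> "DesignSpec":
        return replace(self, variant=variant, gamma=gamma)

    def to_dict(self) -> dict:
        return {
            "s1": self.s1,
            "s2": self.s2,
            "t1": self.t1,
            "rho": self.rho,
            "alpha": self.alpha,
            "target_power": self.target_power,
            "gamma": self.gamma,
            "beta_fd": self.beta_fd,
            "t2_grid": list(self.t2_grid),
            "variant": self.variant,
            "n_draw": self.n_draw,
            "seed": self.seed,
        }


@dataclass
class TrialResult:
    """Complete record of one executed trial."""

    design: DesignSpec
    stopped_at_interim: bool
    interim_decision: interim.InterimDecision
    chosen_t2: Optional[float]
    x_ob1: int
    x_ob2: Optional[int]
    x_ob: Optional[int]
    p_value: Optional[float]
    significant: bool
    threshold_estimate: Optional[analysis.ThresholdEstimate]
    screened_expected: float

    def to_dict(self) -> dict:
        return {
            "variant": self.design.variant,
            "stopped_at_interim": self.stopped_at_interim,
            "chosen_t2": self.chosen_t2,
            "x_ob1": self.x_ob1,
            "x_ob2": self.x_ob2,
            "x_ob": self.x_ob,
            "p_value": self.p_value,
            "significant": self.significant,
            "threshold_estimate": (
                self.threshold_estimate.to_dict() if self.threshold_estimate else None
            ),
            "screened_expected": self.screened_expected,
        }


def generate_stage(
    n: int, t: float, curve: LogisticCurve, rng: np.random.Generator, stage: int = 1
) -> interim.StageData:
    """Simulate one stage: quantiles ~ U[t, 1], responses ~ Bern(pi(B))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= t < 1.0:
        raise ValueError("recruitment threshold must lie in [0, 1)")
    b = rng.uniform(t, 1.0, size=n)
    x = (rng.random(n) < response_rate(curve, b)).astype(int)
    return interim.StageData(b, x, stage=stage)


def _interim_decision(
    design: DesignSpec,
    stage1: interim.StageData,
    fit: Optional[interim.CoefficientDraws],
    rng: np.random.Generator,
) -> interim.InterimDecision:
    x_h2 = design.x_h - stage1.x_ob
    if design.variant in interim.FIXED_VARIANTS:
        return interim.decide_fixed(
            stage1.x_ob,
            design.s1,
            design.s2,
            design.x_h,
            design.beta_fd,
            design.variant,
            threshold=design.t1,
        )
    grid = np.asarray(design.t2_grid)
    if fit is None or fit.degenerate:
        # analytic limits of the predicted power for fits with no finite MLE:
        # no responses -> power 0 everywhere (stop); otherwise the response
        # rate is consistent with the most optimistic curve (continue at the
        # smallest candidate threshold, predicted power 1 in the limit)
        if stage1.x_ob == 0:
            return interim.InterimDecision(
                "stop",
                None,
                design.variant,
                x_h2,
                diagnostics={"degenerate_fit": True},
            )
        return interim.InterimDecision(
            "continue",
            float(grid[0]),
            design.variant,
            x_h2,
            diagnostics={"degenerate_fit": True},
        )
    draws = interim.sample_coefficients(fit, design.n_draw, rng)
    curve = interim.predicted_power_curve(draws, grid, design.s2, x_h2)
    return interim.decide_adaptive(
        curve, design.target_power, design.gamma, design.variant, x_h2
    )


def run_trial(
    design: DesignSpec,
    scenario: Scenario,
    rng: np.random.Generator,
    estimate: bool = True,
    ci_draws: int = 0,
    coverage: float = 0.75,
) -> TrialResult:
    """Execute one complete trial under a data-generating scenario.

    The supplied generator is split into independent substreams for stage-1
    data, interim coefficient draws, stage-2 data and estimation draws, so
    that e.g. changing ``n_draw`` does not perturb recruitment.

    ``estimate=False`` skips threshold estimation (power/TOER studies);
    ``ci_draws`` > 0 additionally computes a resampling interval for T_hat.
    """
    r_stage1, r_coef, r_stage2, r_est = rng.spawn(4)
    stage1 = generate_stage(design.s1, design.t1, scenario.curve, r_stage1, stage=1)
    needs_fit = design.variant in interim.ADAPTIVE_VARIANTS or estimate
    fit1 = interim.fit_stage1_model(stage1) if needs_fit else None
    decision = _interim_decision(design, stage1, fit1, r_coef)

    screen1 = design.s1 / (1.0 - design.t1)
    if decision.action == "stop":
        est = None
        if estimate:
            est = analysis.estimate_threshold(
                stage1,
                scenario.reference_rate,
                n_draw=ci_draws,
                rng=r_est,
                coverage=coverage,
                fit=fit1,
            )
        return TrialResult(
            design=design,
            stopped_at_interim=True,
            interim_decision=decision,
            chosen_t2=None,
            x_ob1=stage1.x_ob,
            x_ob2=None,
            x_ob=None,
            p_value=None,
            significant=False,
            threshold_estimate=est,
            screened_expected=screen1,
        )

    t2 = design.t1 if decision.chosen_t2 is None else float(decision.chosen_t2)
    stage2 = generate_stage(design.s2, t2, scenario.curve, r_stage2, stage=2)
    pooled = interim.StageData.pool(stage1, stage2)
    test = analysis.TestResult.from_counts(
        pooled.x_ob, design.s, design.rho, design.alpha
    )
    est = None
    if estimate:
        est = analysis.estimate_threshold(
            pooled,
            scenario.reference_rate,
            n_draw=ci_draws,
            rng=r_est,
            coverage=coverage,
        )
    return TrialResult(
        design=design,
        stopped_at_interim=False,
        interim_decision=decision,
        chosen_t2=t2,
        x_ob1=stage1.x_ob,
        x_ob2=stage2.x_ob,
        x_ob=pooled.x_ob,
        p_value=test.p_value,
        significant=test.significant,
        threshold_estimate=est,
        screened_expected=screen1 + design.s2 / (1.0 - t2),
    )
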