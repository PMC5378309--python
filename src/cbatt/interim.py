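"""Interim analysis: stage-1 model fit, coefficient resampling and the
beta-binomial predicted-power machinery behind the threshold-adaptation rules.

The interim proceeds in four steps.  (1) Fit a logistic regression of
response on biomarker quantile to the stage-1 subjects.  (2) Propagate the
fit uncertainty by drawing coefficient pairs from a bivariate normal centred
at the MLE with the inverse observed-information covariance.  (3) For each
candidate stage-2 threshold t*, convert every coefficient draw into a subset
response rate Pi~(t*), fit a beta distribution to those draws by moments,
and compute the predicted power: the beta-binomial probability that stage 2
yields at least the outstanding number of responses X_H,2.  (4) Apply one of
five decision rules:

* AD1 — continue at the smallest threshold whose predicted power reaches the
  target, otherwise stop;
* AD2 — like AD1, but if no threshold reaches the target, continue at the
  largest grid threshold provided its predicted power exceeds gamma;
* AD3 — AD2 with gamma = 0: never stops (always falls back to the largest
  threshold);
* FD1 — keep the original threshold, but stop if the beta-binomial
  predictive probability of overall success (with a Beta(X_ob1, S1 - X_ob1)
  posterior on the response rate) falls below the futility bound;
* FD2 — keep the original threshold, never stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import betabinom, binom

from .model import _subset_rate_params

__all__ = [
    "StageData",
    "CoefficientDraws",
    "PredictedPowerCurve",
    "InterimDecision",
    "InsufficientDataError",
    "fit_stage1_model",
    "sample_coefficients",
    "predicted_power",
    "predicted_power_curve",
    "decide_adaptive",
    "decide_fixed",
]

logger = logging.getLogger(__name__)

ADAPTIVE_VARIANTS = ("AD1", "AD2", "AD3")
FIXED_VARIANTS = ("FD1", "FD2")

#: draw sets whose Pi~ variance falls below this are treated as a point mass
ZERO_VARIANCE_TOL = 1e-12
#: Pi~ draws are clamped inside (0, 1) by this margin before the moment fit
PI_CLAMP = 1e-9


class InsufficientDataError(ValueError):
    """Raised when fewer than two subjects are available for the model fit."""


@dataclass
class StageData:
    """Recruited subjects for one stage: biomarker quantiles and responses."""

    quantiles: np.ndarray
    responses: np.ndarray
    stage: int = 1

    def __post_init__(self) -> None:
        self.quantiles = np.asarray(self.quantiles, dtype=float)
        self.responses = np.asarray(self.responses, dtype=int)
        if self.quantiles.shape != self.responses.shape:
            raise ValueError("quantiles and responses must have equal length")
        if self.quantiles.size and (
            self.quantiles.min() < 0.0 or self.quantiles.max() > 1.0
        ):
            raise ValueError("quantiles must lie in [0, 1]")
        if self.responses.size and not np.isin(self.responses, (0, 1)).all():
            raise ValueError("responses must be 0/1")

    @property
    def n(self) -> int:
        return int(self.quantiles.size)

    @property
    def x_ob(self) -> int:
        """Number of observed responses."""
        return int(self.responses.sum())

    @staticmethod
    def pool(*stages: "StageData") -> "StageData":
        return StageData(
            np.concatenate([s.quantiles for s in stages]),
            np.concatenate([s.responses for s in stages]),
            stage=max(s.stage for s in stages),
        )


@dataclass
class CoefficientDraws:
    """Logistic-fit point estimate, covariance and (optionally) MVN draws.

    ``fit_stage1_model`` returns this with ``draws=None``;
    ``sample_coefficients`` fills in the draws.  ``degenerate`` flags fits
    without a finite MLE (all responses identical, or separated data).
    """

    point_estimate: np.ndarray
    covariance: np.ndarray
    draws: Optional[np.ndarray] = None
    degenerate: bool = False
    message: str = ""

    @property
    def n_draw(self) -> int:
        return 0 if self.draws is None else int(self.draws.shape[0])


def fit_stage1_model(data: StageData) -> CoefficientDraws:
    """Maximum-likelihood logistic fit of response on biomarker quantile.

    The covariance is the inverse observed Fisher information.  Degenerate
    data (identical responses, or perfect/quasi separation, where no finite
    MLE exists) are returned flagged rather than raising, since the trial
    rules have defined limiting behaviour for them.
    """
    if data.n < 2:
        raise InsufficientDataError(f"need at least 2 subjects, got {data.n}")
    y = data.responses.astype(float)
    if y.min() == y.max():
        kind = "all responses 1" if y[0] == 1 else "all responses 0"
        return CoefficientDraws(
            point_estimate=np.array([np.nan, np.nan]),
            covariance=np.full((2, 2), np.nan),
            degenerate=True,
            message=f"no finite MLE: {kind}",
        )
    exog = sm.add_constant(data.quantiles, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, exog).fit(disp=0, warn_convergence=False)
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
    except Exception as exc:  # statsmodels raises on exact separation
        return CoefficientDraws(
            point_estimate=np.array([np.nan, np.nan]),
            covariance=np.full((2, 2), np.nan),
            degenerate=True,
            message=f"fit failed ({exc})",
        )
    if (
        not np.all(np.isfinite(params))
        or not np.all(np.isfinite(cov))
        or np.abs(params).max() > 50.0
    ):
        return CoefficientDraws(
            point_estimate=params,
            covariance=cov,
            degenerate=True,
            message="separated or near-separated data: unbounded estimates",
        )
    return CoefficientDraws(point_estimate=params, covariance=cov)


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() >= 0:
        return cov
    logger.warning(
        "covariance not PSD (min eigenvalue %.3g); clipping at zero", vals.min()
    )
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def sample_coefficients(
    fit: CoefficientDraws, n_draw: int, rng: np.random.Generator
) -> CoefficientDraws:
    """Draw coefficient pairs from MVN(point_estimate, covariance).

    A non-PSD covariance (possible with near-separated data) is repaired by
    clipping negative eigenvalues at zero, with a logged warning.
    """
    if fit.degenerate:
        raise ValueError(f"cannot sample from a degenerate fit: {fit.message}")
    if n_draw < 1:
        raise ValueError("n_draw must be >= 1")
    cov = _nearest_psd(np.asarray(fit.covariance, dtype=float))
    draws = rng.multivariate_normal(
        fit.point_estimate, cov, size=n_draw, method="cholesky"
    ) if _is_pd(cov) else rng.multivariate_normal(
        fit.point_estimate, cov, size=n_draw, method="svd"
    )
    return CoefficientDraws(
        point_estimate=fit.point_estimate, covariance=cov, draws=draws
    )


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


@dataclass
class PredictedPowerCurve:
    """Predicted power 1 - beta' over the candidate stage-2 threshold grid."""

    thresholds: np.ndarray
    powers: np.ndarray
    beta_params: np.ndarray  # shape (k, 2), NaN where a point mass was used

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        self.beta_params = np.asarray(self.beta_params, dtype=float)

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "powers": self.powers.tolist(),
            "beta_a": self.beta_params[:, 0].tolist(),
            "beta_b": self.beta_params[:, 1].tolist(),
        }


@dataclass
class InterimDecision:
    """Outcome of the interim analysis."""

    action: str  # "continue" | "stop"
    chosen_t2: Optional[float]
    rule: str
    remaining_required: int
    power_curve: Optional[PredictedPowerCurve] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.action not in ("continue", "stop"):
            raise ValueError("action must be 'continue' or 'stop'")
        if (
            self.action == "continue"
            and self.rule in ADAPTIVE_VARIANTS
            and self.chosen_t2 is None
        ):
            raise ValueError("a continuing adaptive decision must carry chosen_t2")

    def to_dict(self) -> dict:
        out = {
            "action": self.action,
            "chosen_t2": self.chosen_t2,
            "rule": self.rule,
            "remaining_required": self.remaining_required,
            "diagnostics": self.diagnostics,
        }
        if self.power_curve is not None:
            out["power_curve"] = self.power_curve.to_dict()
        return out


def _moment_beta(m: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments Beta(a, b) from mean and variance (elementwise)."""
    # variance of a clamped (0,1) sample can graze m(1-m); keep a, b > 0
    v = np.minimum(v, m * (1.0 - m) * (1.0 - 1e-12))
    common = m * (1.0 - m) / v - 1.0
    return m * common, (1.0 - m) * common


def _tail_powers(
    pi_draws: np.ndarray, s2: int, required: int
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted power per grid column of a (n_draw, k) Pi~ matrix."""
    k = pi_draws.shape[1]
    beta_params = np.full((k, 2), np.nan)
    if required <= 0:
        return np.ones(k), beta_params
    if required > s2:
        return np.zeros(k), beta_params
    clamped = np.clip(pi_draws, PI_CLAMP, 1.0 - PI_CLAMP)
    m = clamped.mean(axis=0)
    v = clamped.var(axis=0)
    powers = np.empty(k)
    point_mass = v < ZERO_VARIANCE_TOL
    if point_mass.any():
        powers[point_mass] = binom.sf(required - 1, s2, m[point_mass])
    if (~point_mass).any():
        a, b = _moment_beta(m[~point_mass], v[~point_mass])
        beta_params[~point_mass, 0] = a
        beta_params[~point_mass, 1] = b
        powers[~point_mass] = betabinom.sf(required - 1, s2, a, b)
    return powers, beta_params


def predicted_power(
    draws: CoefficientDraws, threshold: float, s2: int, required: int
) -> tuple[float, float, float]:
    """Predicted power at one candidate threshold.

    Evaluates the subset rate Pi~(threshold) for every coefficient draw, fits
    Beta(a, b) to those values by moments, and returns
    ``(P(X >= required | X ~ BetaBinomial(s2, a, b)), a, b)``.  A zero-spread
    draw set degenerates to a plain binomial tail (a = b = NaN).  The
    boundary cases are returned, not raised: power 1 when ``required <= 0``
    and power 0 when ``required > s2``.
    """
    if s2 < 1:
        raise ValueError("s2 must be >= 1")
    if draws.draws is None:
        raise ValueError("draws must be sampled first (sample_coefficients)")
    pi = _subset_rate_params(
        draws.draws[:, 0], draws.draws[:, 1], float(threshold)
    ).reshape(-1, 1)
    powers, beta_params = _tail_powers(pi, s2, required)
    return float(powers[0]), float(beta_params[0, 0]), float(beta_params[0, 1])


def predicted_power_curve(
    draws: CoefficientDraws,
    grid: Sequence[float],
    s2: int,
    required: int,
) -> PredictedPowerCurve:
    """Predicted power at every grid threshold, reusing one set of draws."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    if s2 < 1:
        raise ValueError("s2 must be >= 1")
    if draws.draws is None:
        raise ValueError("draws must be sampled first (sample_coefficients)")
    pi = _subset_rate_params(
        draws.draws[:, 0][:, None], draws.draws[:, 1][:, None], grid[None, :]
    )
    powers, beta_params = _tail_powers(pi, s2, required)
    return PredictedPowerCurve(grid, powers, beta_params)


def decide_adaptive(
    curve: PredictedPowerCurve,
    target_power: float,
    gamma: float,
    variant: str,
    remaining_required: int = 0,
) -> InterimDecision:
    """Apply an adaptive threshold-selection rule to a predicted-power curve.

    Continue at the smallest grid threshold whose predicted power reaches
    ``target_power``.  Failing that: AD1 stops; AD2 falls back to the largest
    grid threshold if its predicted power strictly exceeds ``gamma``; AD3
    always falls back to the largest grid threshold.
    """
    if variant not in ADAPTIVE_VARIANTS:
        raise ValueError(f"unknown adaptive variant {variant!r}")
    if variant == "AD1" and gamma != target_power:
        raise ValueError("AD1 requires gamma == target_power")
    if variant == "AD3" and gamma != 0:
        raise ValueError("AD3 requires gamma == 0")
    ok = np.flatnonzero(curve.powers >= target_power)
    if ok.size:
        return InterimDecision(
            "continue",
            float(curve.thresholds[ok[0]]),
            variant,
            remaining_required,
            power_curve=curve,
        )
    max_power = float(curve.powers[-1])
    if variant == "AD3" or (variant == "AD2" and max_power > gamma):
        return InterimDecision(
            "continue",
            float(curve.thresholds[-1]),
            variant,
            remaining_required,
            power_curve=curve,
            diagnostics={"fallback_to_max": True, "max_power": max_power},
        )
    return InterimDecision(
        "stop",
        None,
        variant,
        remaining_required,
        power_curve=curve,
        diagnostics={"max_power": max_power},
    )


def fixed_design_tail(x_ob1: int, s1: int, s2: int, x_h: int) -> float:
    """Predictive probability of overall success under the fixed design.

    P(X_ob >= X_H) where the stage-2 count follows BetaBinomial(S2, X_ob1,
    S1 - X_ob1).  The boundary posteriors are handled as their limits: with
    zero stage-1 responses the predictive response rate collapses to 0, with
    all stage-1 subjects responding it collapses to 1.
    """
    required = x_h - x_ob1
    if required <= 0:
        return 1.0
    if required > s2:
        return 0.0
    if x_ob1 == 0:
        return 0.0  # limit of Beta(eps, s1): all mass at rate 0
    if x_ob1 == s1:
        return 1.0  # limit of Beta(s1, eps): all mass at rate 1
    return float(betabinom.sf(required - 1, s2, x_ob1, s1 - x_ob1))


def decide_fixed(
    x_ob1: int,
    s1: int,
    s2: int,
    x_h: int,
    beta_fd: float,
    variant: str,
    threshold: Optional[float] = None,
) -> InterimDecision:
    """Apply a fixed-threshold interim rule.

    FD2 always continues.  FD1 stops iff the beta-binomial predictive
    probability of reaching ``x_h`` falls strictly below ``1 - beta_fd``
    (with the conventional futility bound 1 - beta_fd = 0.2).  ``threshold``,
    when given, is echoed as the stage-2 recruitment threshold (fixed designs
    keep the stage-1 threshold).
    """
    if variant not in FIXED_VARIANTS:
        raise ValueError(f"unknown fixed variant {variant!r}")
    if not 0 <= x_ob1 <= s1:
        raise ValueError("x_ob1 must lie in [0, s1]")
    required = x_h - x_ob1
    if variant == "FD2":
        return InterimDecision("continue", threshold, variant, required)
    tail = fixed_design_tail(x_ob1, s1, s2, x_h)
    action = "stop" if tail < 1.0 - beta_fd else "continue"
    return InterimDecision(
        action,
        None if action == "stop" else threshold,
        variant,
        required,
        diagnostics={"predictive_probability": tail},
    )
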