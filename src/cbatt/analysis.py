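"""End-of-study inference: the binomial exact test and threshold estimation.

The efficacy test is a one-sided binomial exact test of the pooled response
count against the reference rate rho.  Because recruitment is restricted to
quantiles above max(t1, t2) and the response curve is assumed monotone, a
significant pooled test implies the existence of a subpopulation whose
response rate exceeds rho.

The true threshold T — the smallest quantile whose subset response rate
meets rho — is estimated by refitting the logistic model on all recruited
subjects and taking the grid argmin of |Pi_hat(B) - rho|.  Uncertainty
intervals come from re-estimating the argmin under MVN coefficient draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from . import interim as _interim
from .model import _subset_rate_params, quantile_transform

__all__ = [
    "TestResult",
    "ThresholdEstimate",
    "required_responses",
    "exact_test",
    "estimate_threshold",
    "default_search_grid",
    "raw_threshold",
]


def required_responses(s: int, rho: float, alpha: float) -> int:
    """Minimum responses X_H for a significant exact test at level alpha.

    The smallest integer x with P(X >= x | X ~ Binomial(s, rho)) <= alpha;
    ``s + 1`` if even x = s is not significant.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    x = np.arange(s + 1)
    tails = binom.sf(x - 1, s, rho)
    hits = np.flatnonzero(tails <= alpha)
    return int(hits[0]) if hits.size else s + 1


def exact_test(x_ob: int, s: int, rho: float) -> float:
    """Upper-tail binomial exact p-value P(X >= x_ob | X ~ Binomial(s, rho))."""
    if not 0 <= x_ob <= s:
        raise ValueError("x_ob must lie in [0, s]")
    return float(binom.sf(x_ob - 1, s, rho))


@dataclass(frozen=True)
class TestResult:
    """Binomial exact test outcome; significance uses the p <= alpha convention."""

    x_ob: int
    s: int
    rho: float
    alpha: float
    p_value: float
    significant: bool

    @classmethod
    def from_counts(cls, x_ob: int, s: int, rho: float, alpha: float) -> "TestResult":
        p = exact_test(x_ob, s, rho)
        return cls(x_ob, s, rho, alpha, p, p <= alpha)

    def to_dict(self) -> dict:
        return {
            "x_ob": self.x_ob,
            "s": self.s,
            "rho": self.rho,
            "alpha": self.alpha,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def default_search_grid() -> np.ndarray:
    """Quantile grid 0, 0.001, ..., 0.999 used for the threshold argmin."""
    return np.round(np.arange(0, 1000) / 1000.0, 3)


@dataclass
class ThresholdEstimate:
    """Point estimate T_hat with a resampling interval.

    ``interval`` holds the empirical ((1-coverage)/2, 1-(1-coverage)/2)
    quantiles of the per-draw argmin estimates T~; it is ``None`` when no
    draws were requested.  ``degenerate`` marks estimates that could not be
    computed because the pooled logistic fit had no finite MLE.
    """

    point: float
    interval: Optional[tuple[float, float]]
    coverage: float
    draw_estimates: Optional[np.ndarray] = None
    degenerate: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if self.interval is not None:
            lo, hi = self.interval
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("interval bounds must be ordered quantiles")

    def to_dict(self) -> dict:
        return {
            "point": None if np.isnan(self.point) else self.point,
            "interval": list(self.interval) if self.interval else None,
            "coverage": self.coverage,
            "degenerate": self.degenerate,
            "message": self.message,
        }


def _argmin_threshold(
    delta0, delta1, grid: np.ndarray, rho: float
) -> np.ndarray:
    """Grid argmin of |Pi(B) - rho| per coefficient pair (ties -> smaller B)."""
    delta0 = np.atleast_1d(np.asarray(delta0, dtype=float))
    delta1 = np.atleast_1d(np.asarray(delta1, dtype=float))
    pi = _subset_rate_params(delta0[:, None], delta1[:, None], grid[None, :])
    idx = np.argmin(np.abs(pi - rho), axis=1)  # first index on ties
    return grid[idx]


def estimate_threshold(
    all_data: "_interim.StageData",
    rho: float,
    search_grid: Optional[Sequence[float]] = None,
    n_draw: int = 1000,
    rng: Optional[np.random.Generator] = None,
    coverage: float = 0.75,
    fit: Optional["_interim.CoefficientDraws"] = None,
) -> ThresholdEstimate:
    """Estimate the true threshold T from pooled trial data.

    Fits the logistic model on all subjects (or reuses a supplied ``fit``,
    e.g. the interim fit of a stopped study), takes
    T_hat = argmin_B |Pi_hat(B) - rho| over the search grid, and builds the
    interval from the same argmin applied to ``n_draw`` MVN coefficient
    draws.  ``n_draw = 0`` skips the interval (point estimate only).
    """
    grid = (
        default_search_grid()
        if search_grid is None
        else np.asarray(search_grid, dtype=float)
    )
    if fit is None:
        fit = _interim.fit_stage1_model(all_data)
    if fit.degenerate:
        return ThresholdEstimate(
            point=np.nan,
            interval=None,
            coverage=coverage,
            degenerate=True,
            message=fit.message,
        )
    point = float(
        _argmin_threshold(fit.point_estimate[0], fit.point_estimate[1], grid, rho)[0]
    )
    if n_draw <= 0:
        return ThresholdEstimate(point=point, interval=None, coverage=coverage)
    if rng is None:
        raise ValueError("rng is required when n_draw > 0")
    draws = _interim.sample_coefficients(fit, n_draw, rng)
    t_draws = _argmin_threshold(draws.draws[:, 0], draws.draws[:, 1], grid, rho)
    half = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(t_draws, [half, 1.0 - half])
    return ThresholdEstimate(
        point=point,
        interval=(float(lo), float(hi)),
        coverage=coverage,
        draw_estimates=t_draws,
    )


def raw_threshold(t_hat: float, reference) -> float:
    """Back-transform a quantile threshold to the raw biomarker scale.

    Returns the smallest reference value whose empirical quantile is >= t_hat
    (nearest reference order statistic; no interpolation).
    """
    reference = np.sort(np.asarray(reference, dtype=float))
    quantiles = quantile_transform(reference, reference)
    idx = np.searchsorted(quantiles, t_hat, side="left")
    idx = min(idx, reference.size - 1)
    return float(reference[idx])
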