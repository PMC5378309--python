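"""Biomarker-response model on the quantile scale.

The trial design works with biomarker *quantiles*: each raw biomarker
measurement is mapped to its empirical quantile in a reference population,
so that across the population B ~ Unif[0,1].  Response is modelled with a
logistic curve on the quantile scale,

    pi(B) = expit(delta0 + delta1 * B),

and the quantity the design actually reasons about is the *subset response
rate* — the mean response probability among subjects with biomarker quantile
at or above a threshold B,

    Pi(B) = E[pi(U) | U >= B],  U ~ Unif[0,1]
          = ln[(1 + exp(delta0 + delta1)) / (1 + exp(delta0 + delta1 * B))]
            / (delta1 * (1 - B)),

which has a closed form because the integral of the logistic CDF is the
softplus function.  This module provides the curve type, both rates,
intercept calibration (solving for delta0 so a target subset rate is hit)
and the empirical quantile transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "LogisticCurve",
    "SubsetRate",
    "Scenario",
    "InvalidModelError",
    "CalibrationError",
    "response_rate",
    "subset_rate",
    "calibrate_intercept",
    "true_threshold",
    "quantile_transform",
]

#: below this |delta1| the closed form (which divides by delta1) switches to
#: its analytic flat-curve limit expit(delta0)
DELTA1_SWITCH_TOL = 1e-8


class InvalidModelError(ValueError):
    """Raised when logistic coefficients are not finite."""


class CalibrationError(RuntimeError):
    """Raised when no intercept in the search bracket attains the target rate."""


@dataclass(frozen=True)
class LogisticCurve:
    """Logistic biomarker-response curve on the quantile scale.

    Parameters
    ----------
    delta0 : float
        Log-odds of response at biomarker quantile 0.
    delta1 : float
        Log odds ratio per unit increase in biomarker quantile.
    """

    delta0: float
    delta1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta0) and math.isfinite(self.delta1)):
            raise InvalidModelError(
                f"non-finite logistic coefficients ({self.delta0}, {self.delta1})"
            )


@dataclass(frozen=True)
class SubsetRate:
    """A subset response rate Pi evaluated at a particular quantile."""

    at: float
    value: float


@dataclass(frozen=True)
class Scenario:
    """A data-generating scenario for the simulation study.

    ``true_threshold`` is the smallest quantile T with Pi(T) = reference_rate
    (the boundary of the responsive subpopulation); it is ``None`` for
    scenarios in which no such quantile exists (null scenarios, and flat
    curves whose constant rate differs from the reference rate).
    ``hypothesis_threshold`` is the analogous quantile for the required
    response rate R_H = X_H / S, when known.
    """

    curve: LogisticCurve
    reference_rate: float
    true_threshold: Optional[float] = None
    hypothesis_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.reference_rate < 1.0:
            raise ValueError("reference_rate must be in (0, 1)")
        if self.true_threshold is not None:
            t = self.true_threshold
            if not 0.0 <= t <= 1.0:
                raise ValueError("true_threshold must be a quantile in [0, 1]")
            if abs(subset_rate(self.curve, t) - self.reference_rate) >= 1e-6:
                raise ValueError(
                    "true_threshold inconsistent with curve: "
                    f"Pi({t}) != {self.reference_rate}"
                )


def _check_quantile(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any((b < 0.0) | (b > 1.0)):
        raise ValueError("biomarker quantile must lie in [0, 1]")
    return b


def _log1pexp(z: np.ndarray) -> np.ndarray:
    # softplus ln(1+e^z), stable for |z| up to well past 700
    return np.logaddexp(0.0, z)


def response_rate(curve: LogisticCurve, b):
    """Point response rate pi(B) = expit(delta0 + delta1 * B).

    Accepts a scalar or array of quantiles in [0, 1].
    """
    b = _check_quantile(b)
    out = expit(curve.delta0 + curve.delta1 * b)
    return float(out) if out.ndim == 0 else out


def _subset_rate_params(delta0, delta1, b):
    """Vectorised Pi(B) for arrays of coefficients and/or quantiles.

    Broadcasts ``delta0``, ``delta1`` and ``b`` together.  Uses the closed
    form away from the two removable singularities (delta1 -> 0 and b -> 1),
    and the analytic limits there.
    """
    delta0, delta1, b = np.broadcast_arrays(
        np.asarray(delta0, dtype=float),
        np.asarray(delta1, dtype=float),
        np.asarray(b, dtype=float),
    )
    flat = np.abs(delta1) < DELTA1_SWITCH_TOL
    at_one = b >= 1.0
    # masked denominators keep the closed-form branch free of 0/0 warnings
    safe_d1 = np.where(flat, 1.0, delta1)
    safe_b = np.where(at_one, 0.0, b)
    closed = (
        _log1pexp(delta0 + delta1) - _log1pexp(delta0 + safe_d1 * safe_b)
    ) / (safe_d1 * (1.0 - safe_b))
    limit_b1 = expit(delta0 + delta1)  # Pi(1) = pi(1)
    limit_flat = expit(delta0)
    out = np.where(at_one, limit_b1, np.where(flat, limit_flat, closed))
    # guard against tiny negative round-off at extreme coefficients
    return np.clip(out, 0.0, 1.0)


def subset_rate(curve: LogisticCurve, b):
    """Subset response rate Pi(B): mean of pi over quantiles in [B, 1].

    At B = 1 the analytic limit pi(1) is returned; for |delta1| below
    ``DELTA1_SWITCH_TOL`` the flat-curve limit expit(delta0) is returned.
    """
    b = _check_quantile(b)
    out = _subset_rate_params(curve.delta0, curve.delta1, b)
    return float(out) if out.ndim == 0 else out


def calibrate_intercept(
    delta1: float, anchor_b: float, anchor_rate: float
) -> LogisticCurve:
    """Solve for the intercept so that Pi(anchor_b) equals anchor_rate.

    Pi is strictly increasing in delta0, so the root is unique; it is found
    by Brent's method on delta0 in [-50, 50].
    """
    if delta1 < 0:
        raise ValueError("delta1 must be non-negative")
    if not 0.0 <= anchor_b < 1.0:
        raise ValueError("anchor_b must lie in [0, 1)")
    if not 0.0 < anchor_rate < 1.0:
        raise ValueError("anchor_rate must lie in (0, 1)")
    if abs(delta1) < DELTA1_SWITCH_TOL:
        return LogisticCurve(float(logit(anchor_rate)), float(delta1))

    def f(d0: float) -> float:
        return float(_subset_rate_params(d0, delta1, anchor_b)) - anchor_rate

    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"no intercept in [-50, 50] gives Pi({anchor_b}) = {anchor_rate} "
            f"with delta1 = {delta1}"
        )
    d0 = brentq(f, lo, hi, xtol=1e-12)
    return LogisticCurve(float(d0), float(delta1))


def true_threshold(curve: LogisticCurve, rate: float) -> Optional[float]:
    """Smallest quantile T with Pi(T) = rate, or None if Pi never reaches it.

    Returns 0.0 when the whole population already meets the rate
    (Pi(0) >= rate), matching the convention that a flat curve above the
    reference rate has threshold zero; returns None for flat curves below
    the rate and for curves whose maximum Pi stays below it.
    """
    if subset_rate(curve, 0.0) >= rate:
        return 0.0
    if subset_rate(curve, 1.0) <= rate:
        return None
    return float(
        brentq(lambda b: subset_rate(curve, b) - rate, 0.0, 1.0, xtol=1e-12)
    )


def quantile_transform(values, reference) -> np.ndarray:
    """Map raw biomarker values to empirical quantiles of a reference sample.

    The convention is quantile = (number of reference values <= v) / n, i.e.
    rank with ties assigned their maximum rank: the reference maximum maps
    to 1 and values below the reference minimum map to 0.  The transform is
    monotone non-decreasing in the raw value.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("reference sample must be non-empty")
    values = np.asarray(values, dtype=float)
    ref_sorted = np.sort(reference)
    ranks = np.searchsorted(ref_sorted, values, side="right")
    return ranks / reference.size
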