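"""Applying the design to subject-level data.

This module covers the retrospective-application workflow: read a delimited
table of subjects (``subject_id,biomarker,response``), transform the raw
biomarker values to empirical quantiles against a reference sample, emulate
sequential recruitment through both stages, run the interim and final
analyses, and report the estimated threshold on both the quantile and the
raw biomarker scale.

No clinical dataset ships with the package; :func:`generate_records`
produces synthetic subject tables from a known biomarker-response curve with
a monotone raw-scale transform, which is what the tests and examples use.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis, interim
from .model import LogisticCurve, quantile_transform, response_rate
from .simulate import DesignSpec

__all__ = [
    "SubjectRecord",
    "RecruitmentError",
    "load_records",
    "generate_records",
    "recruit_sequentially",
    "run_application",
]

logger = logging.getLogger(__name__)

COLUMNS = ("subject_id", "biomarker", "response")


class RecruitmentError(RuntimeError):
    """Raised when fewer eligible subjects are available than requested."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: opaque id, raw biomarker measurement, binary response."""

    subject_id: str
    biomarker_raw: float
    response: int


def load_records(path) -> pd.DataFrame:
    """Read a subject table (CSV with header subject_id,biomarker,response).

    Records with a missing response (empty field) are dropped with a logged
    count; biomarker values must be finite.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table lacks columns: {missing}")
    n_missing = int(df["response"].isna().sum())
    if n_missing:
        logger.info("dropping %d records with missing response", n_missing)
        df = df.dropna(subset=["response"])
    if not np.isfinite(df["biomarker"].to_numpy(dtype=float)).all():
        raise ValueError("biomarker values must be finite")
    df = df.astype({"biomarker": float, "response": int})
    if not df["response"].isin((0, 1)).all():
        raise ValueError("response must be coded 0/1")
    return df.reset_index(drop=True)


def generate_records(
    n: int,
    curve: LogisticCurve,
    rng: np.random.Generator,
    raw_scale: float = 50.0,
) -> pd.DataFrame:
    """Synthetic subject table drawn from a biomarker-response curve.

    Quantiles are uniform on [0, 1]; the raw biomarker is a monotone
    (exponential-quantile) transform of the quantile, mimicking the
    right-skewed assay distributions typical of receptor measurements.
    """
    b = rng.uniform(0.0, 1.0, size=n)
    raw = -raw_scale * np.log1p(-b * (1 - 1e-12))
    x = (rng.random(n) < response_rate(curve, b)).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "biomarker": np.round(raw, 4),
            "response": x,
        }
    )


def recruit_sequentially(
    records: pd.DataFrame,
    threshold: float,
    n: int,
    reference: Sequence[float],
    exclude: Optional[set] = None,
    stage: int = 1,
) -> tuple[interim.StageData, list]:
    """Recruit the first ``n`` eligible subjects in table order.

    A subject is eligible when its biomarker quantile (relative to
    ``reference``) is at least ``threshold`` and it has not been recruited
    before (``exclude``).  Raises :class:`RecruitmentError` naming the
    shortfall when fewer than ``n`` are available.
    """
    exclude = exclude or set()
    q = quantile_transform(records["biomarker"].to_numpy(), reference)
    eligible = (q >= threshold) & ~records["subject_id"].isin(exclude).to_numpy()
    idx = np.flatnonzero(eligible)
    if idx.size < n:
        raise RecruitmentError(
            f"requested {n} subjects at threshold {threshold}, "
            f"only {idx.size} eligible"
        )
    take = idx[:n]
    data = interim.StageData(
        q[take], records["response"].to_numpy()[take], stage=stage
    )
    return data, records["subject_id"].to_numpy()[take].tolist()


def run_application(
    records: pd.DataFrame,
    design: DesignSpec,
    reference: Sequence[float],
    rng: np.random.Generator,
    coverage: float = 0.75,
) -> dict:
    """Run the full two-stage workflow on a subject table.

    Stage 1 recruits the first ``s1`` subjects above ``t1``; the interim
    applies the design's rule; stage 2 (if reached) recruits ``s2`` further
    subjects above the chosen threshold; the final exact test and the
    threshold estimate (quantile and raw biomarker scale) are reported.
    Randomness enters only through the MVN coefficient draws.
    """
    r_coef, r_est = rng.spawn(2)
    reference = np.asarray(reference, dtype=float)
    stage1, ids1 = recruit_sequentially(
        records, design.t1, design.s1, reference, stage=1
    )
    fit1 = interim.fit_stage1_model(stage1)
    x_h = design.x_h
    x_h2 = x_h - stage1.x_ob
    if design.variant in interim.FIXED_VARIANTS:
        decision = interim.decide_fixed(
            stage1.x_ob, design.s1, design.s2, x_h, design.beta_fd,
            design.variant, threshold=design.t1,
        )
    else:
        if fit1.degenerate:
            raise RuntimeError(
                f"stage-1 model fit is degenerate ({fit1.message}); "
                "the adaptive interim cannot be computed"
            )
        draws = interim.sample_coefficients(fit1, design.n_draw, r_coef)
        curve = interim.predicted_power_curve(
            draws, np.asarray(design.t2_grid), design.s2, x_h2
        )
        decision = interim.decide_adaptive(
            curve, design.target_power, design.gamma, design.variant, x_h2
        )

    report: dict = {
        "design": design.to_dict(),
        "x_h": x_h,
        "stage1": {"n": stage1.n, "x_ob1": stage1.x_ob, "subject_ids": ids1},
        "interim": decision.to_dict(),
    }
    if decision.action == "stop":
        est = analysis.estimate_threshold(
            stage1, design.rho, n_draw=design.n_draw, rng=r_est,
            coverage=coverage, fit=fit1,
        )
        report["final"] = None
        report["threshold"] = _threshold_report(est, reference)
        return report

    t2 = design.t1 if decision.chosen_t2 is None else float(decision.chosen_t2)
    stage2, ids2 = recruit_sequentially(
        records, t2, design.s2, reference, exclude=set(ids1), stage=2
    )
    pooled = interim.StageData.pool(stage1, stage2)
    test = analysis.TestResult.from_counts(
        pooled.x_ob, design.s, design.rho, design.alpha
    )
    est = analysis.estimate_threshold(
        pooled, design.rho, n_draw=design.n_draw, rng=r_est, coverage=coverage
    )
    report["stage2"] = {
        "n": stage2.n,
        "t2": t2,
        "x_ob2": stage2.x_ob,
        "subject_ids": ids2,
    }
    report["final"] = test.to_dict()
    report["threshold"] = _threshold_report(est, reference)
    return report


def _threshold_report(
    est: analysis.ThresholdEstimate, reference: np.ndarray
) -> dict:
    out = est.to_dict()
    if not est.degenerate:
        out["point_raw"] = analysis.raw_threshold(est.point, reference)
        if est.interval is not None:
            out["interval_raw"] = [
                analysis.raw_threshold(q, reference) for q in est.interval
            ]
    return out


def manifest(design: DesignSpec, seed: int, extra: Optional[dict] = None) -> dict:
    """Run manifest: seed, package version and a hash of the configuration."""
    from . import __version__

    config = json.dumps(design.to_dict(), sort_keys=True)
    out = {
        "seed": seed,
        "cbatt_version": __version__,
        "config_sha256": hashlib.sha256(config.encode()).hexdigest(),
    }
    if extra:
        out.update(extra)
    return out
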