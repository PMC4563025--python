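"""Learning-efficiency metrics computed from prediction sequences.

Four measures summarise how well a learner tracks the mean of a variable
reward distribution: overall performance error (mean |prediction - EV| over
all trials of a condition), final performance error and final prediction
instability (mean error and sample SD of predictions over the final short
block, trials 36-42), and performance dissimilarity (sample SD of overall
error across the three reward-SD levels, after averaging the two EV
conditions within each level). A per-participant least-squares line of
initial learning rate against log SD provides the slope-based alternative
adaptation measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerformanceSummary",
    "overall_performance_error",
    "final_block_metrics",
    "performance_dissimilarity",
    "fit_line",
    "condition_metrics",
    "cohort_metrics",
    "FINAL_BLOCK",
]

#: Condition-local trials of the final short block (inclusive, 1-based).
FINAL_BLOCK = (36, 42)


def overall_performance_error(predictions, ev: float) -> float:
    """Mean absolute deviation of predictions from the EV."""
    p = np.asarray(predictions, float)
    if p.size == 0:
        raise ValueError("predictions must be non-empty")
    return float(np.mean(np.abs(p - ev)))


def final_block_metrics(predictions, ev: float) -> tuple[float, float]:
    """(final performance error, final prediction instability).

    Mean |prediction - EV| and sample SD of predictions over condition-local
    trials 36-42.
    """
    p = np.asarray(predictions, float)
    lo, hi = FINAL_BLOCK
    if p.size < hi:
        raise ValueError(f"need at least {hi} trials, got {p.size}")
    block = p[lo - 1 : hi]
    return float(np.mean(np.abs(block - ev))), float(np.std(block, ddof=1))


def performance_dissimilarity(errors_by_sd) -> float:
    """Sample SD of overall performance error across the SD levels.

    ``errors_by_sd`` maps SD level (or SD value) to one error per level;
    the two EV conditions sharing an SD must already be averaged.
    """
    if isinstance(errors_by_sd, dict):
        vals = list(errors_by_sd.values())
    else:
        vals = list(errors_by_sd)
    if len(vals) < 2:
        raise ValueError("need at least two SD levels")
    if any(v is None or not np.isfinite(v) for v in vals):
        raise ValueError("missing SD-level error")
    return float(np.std(vals, ddof=1))


def fit_line(x, y) -> tuple[float, float, float]:
    """Ordinary least-squares line: (slope, intercept, R^2).

    Used for per-participant learning-rate-vs-(log)SD slopes and for
    comparing how well log SD predicts fitted parameters.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or np.allclose(x, x[0]):
        raise ValueError("need at least two distinct x values")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):  # constant y: no variance to explain
        r2 = 0.0
    return float(res.slope), float(res.intercept), r2


@dataclass
class PerformanceSummary:
    """Per-participant learning-efficiency summary."""

    participant_id: object
    overall_error: float  # mean over the six conditions
    final_error: float
    final_instability: float
    dissimilarity: float  # across SD levels
    error_by_sd: dict  # sd_target -> overall error (EVs averaged)


def condition_metrics(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per participant x condition metrics from a tidy trial table."""
    rows = []
    for (pid, cid), grp in dataset.groupby(["participant_id", "condition_id"]):
        grp = grp.sort_values("trial_in_condition")
        preds = grp["prediction"].to_numpy(float)
        ev = float(grp["ev"].iloc[0])
        fin_err, fin_inst = final_block_metrics(preds, ev)
        rows.append(
            {
                "participant_id": pid,
                "condition_id": cid,
                "sd_target": float(grp["sd_target"].iloc[0]),
                "sd_level": grp["sd_level"].iloc[0],
                "ev": ev,
                "overall_error": overall_performance_error(preds, ev),
                "final_error": fin_err,
                "final_instability": fin_inst,
            }
        )
    return pd.DataFrame(rows)


def cohort_metrics(dataset: pd.DataFrame) -> tuple[pd.DataFrame, list[PerformanceSummary]]:
    """Condition-level table plus per-participant summaries."""
    cond = condition_metrics(dataset)
    summaries = []
    for pid, grp in cond.groupby("participant_id"):
        by_sd = grp.groupby("sd_target")["overall_error"].mean().to_dict()
        summaries.append(
            PerformanceSummary(
                participant_id=pid,
                overall_error=float(grp["overall_error"].mean()),
                final_error=float(grp["final_error"].mean()),
                final_instability=float(grp["final_instability"].mean()),
                dissimilarity=performance_dissimilarity(by_sd),
                error_by_sd=by_sd,
            )
        )
    return cond, summaries
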