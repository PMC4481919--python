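"""Robust outlier screening with the median absolute deviation (MAD).

The MAD — the median of absolute deviations from the median,
``MAD = median_i(|x_i - median_j(x_j)|)`` — is a robust scale
estimator: a single wild value cannot inflate it the way it inflates a
standard deviation.  Participants are screened by comparing each
summary metric (by default the global alpha coverage of their heat
maps, their total fixation count and their total correct answers) to
the cohort median in MAD units; any metric beyond ``k`` MADs flags the
participant as an outlier.

The raw MAD is used by default (no 1.4826 normal-consistency factor);
pass ``scale="normal"`` where a normal-consistent estimate is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "mad",
    "mad_scores",
    "flag_outliers",
    "OutlierDecision",
    "participant_outlier_decision",
    "DEFAULT_METRICS",
]

#: Normal-consistency factor making the MAD estimate sigma for Gaussians.
NORMAL_CONSISTENCY = 1.4826022185056018

#: Metrics entering the participant-level decision by default.
DEFAULT_METRICS = ("global_alpha", "fix_total_count", "total_correct")


def mad(values: Sequence[float], scale: str = "raw") -> float:
    """Median absolute deviation of ``values``.

    Medians of even-length samples are the midpoint of the two central
    order statistics.  ``scale="normal"`` multiplies by 1.4826 so the
    result estimates the standard deviation under normality.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mad of an empty sequence is undefined")
    if not np.isfinite(arr).all():
        raise ValueError("mad requires finite values")
    m = float(np.median(np.abs(arr - np.median(arr))))
    if scale == "raw":
        return m
    if scale == "normal":
        return m * NORMAL_CONSISTENCY
    raise ValueError("scale must be 'raw' or 'normal'")


def mad_scores(values: Sequence[float], scale: str = "raw") -> np.ndarray:
    """|x - median| / MAD per value; +inf off-median when MAD is 0."""
    arr = np.asarray(values, dtype=float)
    med = np.median(arr)
    m = mad(arr, scale=scale)
    dev = np.abs(arr - med)
    if m == 0:
        return np.where(dev > 0, np.inf, 0.0)
    return dev / m


def flag_outliers(values: Sequence[float], k: float = 3.0, scale: str = "raw") -> np.ndarray:
    """Boolean mask: True where ``|x - median| > k * MAD``.

    With a degenerate MAD of 0 (at least half the values identical) any
    value off the median is flagged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    return mad_scores(values, scale=scale) > k


@dataclass
class OutlierDecision:
    """Per-participant screening outcome."""

    participant_id: str
    metric_values: dict[str, float]
    mad_scores: dict[str, float]
    flagged_metrics: list[str] = field(default_factory=list)

    @property
    def is_outlier(self) -> bool:
        return bool(self.flagged_metrics)


def participant_outlier_decision(
    summaries: pd.DataFrame,
    k: float = 3.0,
    metrics: Sequence[str] = DEFAULT_METRICS,
    scale: str = "raw",
) -> list[OutlierDecision]:
    """Screen a cohort of participant summaries, one decision per row.

    ``summaries`` needs a ``participant_id`` column plus the metric
    columns.  Each metric is screened independently across the cohort;
    a participant flagged on **any** metric is an outlier (OR
    combination).  At least three participants are required for a
    meaningful median.
    """
    if len(summaries) < 3:
        raise ValueError("outlier screening needs a cohort of at least 3 participants")
    missing = [m for m in metrics if m not in summaries.columns]
    if missing:
        raise KeyError(f"summary table is missing metric columns: {missing}")
    scores = {m: mad_scores(summaries[m].to_numpy(), scale=scale) for m in metrics}
    flags = {m: flag_outliers(summaries[m].to_numpy(), k=k, scale=scale) for m in metrics}
    decisions = []
    for i, pid in enumerate(summaries["participant_id"]):
        decisions.append(
            OutlierDecision(
                participant_id=str(pid),
                metric_values={m: float(summaries[m].iloc[i]) for m in metrics},
                mad_scores={m: float(scores[m][i]) for m in metrics},
                flagged_metrics=[m for m in metrics if flags[m][i]],
            )
        )
    return decisions
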