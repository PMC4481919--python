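"""Cohort summaries, weak-performer thresholding and Mann-Whitney tests.

The analysis workflow for the puzzle assessment is:

1. :func:`summarize_cohort` — per-level and total mean (SD) of
   completion time and correct answers;
2. :func:`performance_threshold` — the weak-performer cut-off
   ``ceil(mean - SD)`` of total correct answers (sample SD, ddof=1,
   which reproduces the published 2.20 for the bundled cohort);
3. :func:`select_extreme_groups` — everyone below the threshold forms
   the weakest group; an equally sized best group is taken from the top
   of the score distribution (ties broken by lower total time, then id);
4. :func:`mann_whitney_u` — rank-based comparison of the two small
   groups, metric by metric, reporting the conventional
   ``U = min(U_a, U_b)``.

U is computed with midranks, so tied observations contribute half a
pair each.  Two p-value conventions are available: the one-sided
normal approximation with continuity correction (the default, matching
how small-U tables are usually read) and the exact permutation
distribution, preferred for tie-free samples up to n=10 and available
via ``method="exact"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gaze_io import CohortTable

__all__ = [
    "GroupComparison",
    "summarize_cohort",
    "performance_threshold",
    "select_extreme_groups",
    "mann_whitney_u",
    "comparison_grid",
]


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one two-group Mann-Whitney comparison."""

    metric: str
    n_a: int
    n_b: int
    u_a: float
    u_b: float
    u: float  # min(u_a, u_b)
    p: float
    method: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.u <= self.n_a * self.n_b / 2 + 1e-9
        assert 0.0 <= self.p <= 1.0


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Mean and sample SD of time and correct answers, per level and total.

    Returns a frame indexed ``level1..level4, total`` with columns
    ``time_mean, time_sd, correct_mean, correct_sd``.
    """
    df = table.data
    if not len(df):
        raise ValueError("cohort table is empty")
    rows = {}
    for i in (1, 2, 3, 4):
        rows[f"level{i}"] = (
            df[f"time_level{i}"].mean(), df[f"time_level{i}"].std(ddof=1),
            df[f"correct_level{i}"].mean(), df[f"correct_level{i}"].std(ddof=1),
        )
    rows["total"] = (
        df["total_time"].mean(), df["total_time"].std(ddof=1),
        df["total_correct"].mean(), df["total_correct"].std(ddof=1),
    )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["time_mean", "time_sd", "correct_mean", "correct_sd"]
    )
    return out.fillna(0.0)  # single-participant cohorts have undefined sample SD


def performance_threshold(total_correct: Sequence[float]) -> tuple[int, float]:
    """Weak-performer cut-off from total correct answers.

    Returns ``(threshold, unrounded)`` where ``unrounded = mean - SD``
    (sample SD) and ``threshold = ceil(unrounded)``: participants whose
    total is strictly below the threshold are weak performers.
    """
    arr = np.asarray(total_correct, dtype=float)
    if arr.size < 2:
        raise ValueError("threshold needs at least two scores")
    unrounded = float(arr.mean() - arr.std(ddof=1))
    return math.ceil(unrounded), unrounded


def select_extreme_groups(
    table: CohortTable, threshold: int
) -> tuple[list, list]:
    """Weakest performers and an equally sized best group.

    Weakest: every participant with ``total_correct < threshold``.
    Best: the same number of participants with the highest totals,
    ties broken by lower ``total_time`` and then by id.  Raises if the
    remaining pool is too small to match the weakest group.
    """
    df = table.data
    weak = df.loc[df["total_correct"] < threshold]
    weak_ids = sorted(weak["participant_id"].tolist())
    n = len(weak_ids)
    pool = df.loc[~df["participant_id"].isin(weak_ids)]
    if len(pool) < n:
        raise ValueError(
            f"cannot match {n} weakest performers: only {len(pool)} others available"
        )
    best = pool.sort_values(
        ["total_correct", "total_time", "participant_id"],
        ascending=[False, True, True],
    ).head(n)
    return weak_ids, sorted(best["participant_id"].tolist())


def _u_midrank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """U statistics of both groups via midranks of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    r_a = ranks[: len(a)].sum()
    u_a = r_a - len(a) * (len(a) + 1) / 2.0
    return float(u_a), float(len(a) * len(b) - u_a)


def _p_normal_cc(u_min: float, n_a: int, n_b: int, ties: np.ndarray) -> float:
    """One-sided normal approximation with continuity correction.

    Uses the tie-corrected variance of U; the probability is that of
    observing a U at most the reported minimum under the null.
    """
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    tie_term = float(((ties**3 - ties) / (n * (n - 1))).sum()) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (u_min + 0.5 - mu) / math.sqrt(var)
    return float(stats.norm.cdf(z))


def _p_exact(a: np.ndarray, b: np.ndarray, u_a: float, u_b: float) -> float:
    """Exact one-sided permutation tail P(U <= min U), tie-free samples."""
    alternative = "less" if u_a <= u_b else "greater"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact")
    return float(res.pvalue)


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    method: str = "auto",
) -> GroupComparison:
    """Mann-Whitney comparison of two independent samples.

    ``U_a`` counts, over all cross pairs, how often a value of ``a``
    exceeds a value of ``b`` (ties counting one half); the reported
    ``u`` is ``min(U_a, U_b)``, so small values indicate separation.

    ``method``: ``"normal_cc"`` — one-sided normal approximation with
    continuity correction (tie-corrected variance); ``"exact"`` — exact
    permutation tail, valid only without ties; ``"auto"`` (default) —
    normal approximation, the convention small-sample U tables follow.
    """
    arr_a = np.asarray(a, dtype=float)
    arr_b = np.asarray(b, dtype=float)
    if arr_a.size == 0 or arr_b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_a, u_b = _u_midrank(arr_a, arr_b)
    u_min = min(u_a, u_b)
    pooled = np.concatenate([arr_a, arr_b])
    _, counts = np.unique(pooled, return_counts=True)
    has_ties = bool((counts > 1).any())
    if method == "exact":
        if has_ties:
            raise ValueError("exact permutation p is only available without ties")
        p = _p_exact(arr_a, arr_b, u_a, u_b)
        used = "exact"
    elif method in ("auto", "normal_cc"):
        p = _p_normal_cc(u_min, arr_a.size, arr_b.size, counts.astype(float))
        used = "normal_cc"
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        metric=metric,
        n_a=arr_a.size,
        n_b=arr_b.size,
        u_a=u_a,
        u_b=u_b,
        u=u_min,
        p=p,
        method=used,
    )


def comparison_grid(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    metrics: Sequence[str],
    method: str = "auto",
) -> pd.DataFrame:
    """Run :func:`mann_whitney_u` per metric column of two group frames.

    Returns a frame indexed by metric with columns ``u`` and ``p`` —
    the comparison grid the small-group analysis reports.
    """
    rows = {}
    for m in metrics:
        cmp = mann_whitney_u(group_a[m], group_b[m], metric=m, method=method)
        rows[m] = (cmp.u, cmp.p)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["u", "p"])
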