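"""Bundled reference tables from the pilot attention-assessment study.

The package ships the published per-participant summaries of a pilot
cohort of 32 schoolchildren who solved a four-level puzzle task (50 s
and 4 items per level) while their gaze was recorded:

* :func:`load_cohort_scores` — per-level completion times and correct
  answers for all 32 participants;
* :func:`load_fixation_summary` — per-level fixation counts and mean
  fixation durations for the four best and four weakest performers.

These tables are the desk-checkable inputs for the group-comparison
workflow (performance thresholding, extreme-group selection and
Mann-Whitney tests) and for worked examples in the documentation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .gaze_io import CohortTable

__all__ = ["load_cohort_scores", "load_fixation_summary"]


def load_cohort_scores() -> CohortTable:
    """The 32-participant performance table (times in s, correct counts)."""
    with (resources.files("gazelab") / "data" / "cohort_scores.csv").open() as fh:
        return CohortTable(pd.read_csv(fh))


def load_fixation_summary(group: str) -> pd.DataFrame:
    """Per-level fixation summaries for one extreme group.

    Parameters
    ----------
    group
        ``"best"`` (the four participants with 15/16 correct answers) or
        ``"weakest"`` (the four scoring below the weak-performer
        threshold of 10).

    Returns
    -------
    DataFrame with one row per participant and, per level, the fixation
    count (``fix_count_level*``) and the mean and SD of fixation
    duration in ms (``fix_avgdur_level*``, ``fix_sddur_level*``).
    """
    if group not in ("best", "weakest"):
        raise ValueError("group must be 'best' or 'weakest'")
    name = f"fixation_summary_{group}.csv"
    with (resources.files("gazelab") / "data" / name).open() as fh:
        return pd.read_csv(fh)
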