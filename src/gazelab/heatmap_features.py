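"""Fixation-count heat maps, quadrant statistics and the 34-feature vector.

A heat map accumulates one radially decaying kernel per fixation on a
pixel grid; its 8-bit alpha layer (intensity rescaled with saturation)
summarises where and how much a participant fixated.  The screen is
also partitioned into a 3x3 grid of quadrants labelled A1..C3 (rows
A-C top to bottom, columns 1-3 left to right) and per-quadrant
fixation counts and mean durations are computed directly from fixation
centroids.

:func:`assemble_features` combines the gaze-derived metrics of a
participant's four levels with the performance row of the cohort table
and an outlier flag into the fixed 34-entry feature vector used by the
classification stage: the outlier/normal flag, global alpha coverage,
global fixation count and duration statistics, 9 quadrant counts,
9 quadrant mean durations, 4 per-level times plus the total, and
4 per-level correct counts plus the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze_io import Fixation, FixationRecord, LEVELS
from .ivt_filter import ScreenGeometry

__all__ = [
    "HeatMap",
    "QUADRANT_LABELS",
    "FEATURE_NAMES",
    "render_heatmap",
    "alpha_coverage",
    "quadrant_of",
    "quadrant_stats",
    "assemble_features",
    "features_frame",
    "save_alpha_png",
]

#: Quadrant labels, row-major from the top-left of the screen.
QUADRANT_LABELS = tuple(f"{r}{c}" for r in "ABC" for c in (1, 2, 3))


@dataclass
class HeatMap:
    """Accumulated fixation intensity on the pixel grid plus its alpha layer.

    ``intensity`` is the raw non-negative accumulator (one unit-peak
    kernel added per fixation).  ``saturation`` is the intensity mapped
    to full (255) alpha; intensities at or above it saturate.
    """

    intensity: np.ndarray
    saturation: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity.ndim != 2:
            raise ValueError("intensity grid must be 2-D (height x width)")
        if (self.intensity < 0).any():
            raise ValueError("intensity must be non-negative")
        if self.saturation <= 0:
            raise ValueError("saturation must be positive")

    @property
    def alpha(self) -> np.ndarray:
        """8-bit alpha layer: intensity rescaled to 0-255 with saturation."""
        scaled = np.clip(self.intensity / self.saturation, 0.0, 1.0)
        return np.round(scaled * 255.0).astype(np.uint8)


def _kernel(radius_px: int) -> np.ndarray:
    """Unit-peak linear radial falloff kernel of the given radius."""
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return np.maximum(0.0, 1.0 - np.hypot(xx, yy) / r)


def render_heatmap(
    fixations: Sequence[Fixation],
    geometry: ScreenGeometry | None = None,
    kernel_radius_px: int = 50,
    saturation: float = 1.0,
) -> HeatMap:
    """Accumulate one kernel per fixation into a screen-sized intensity grid.

    Each fixation adds a unit-peak, linearly decaying radial kernel at
    its centroid (converted to pixels and clamped into the screen).
    Intensity is strictly additive, so N coincident fixations produce
    exactly N times the intensity of one before the alpha saturation.
    """
    geometry = geometry or ScreenGeometry()
    h, w = geometry.height_px, geometry.width_px
    grid = np.zeros((h, w))
    if fixations:
        kern = _kernel(kernel_radius_px)
        r = kernel_radius_px
        xs = np.array([f.x for f in fixations])
        ys = np.array([f.y for f in fixations])
        px, py = geometry.to_px(xs, ys)
        px = np.clip(np.round(px).astype(int), 0, w - 1)
        py = np.clip(np.round(py).astype(int), 0, h - 1)
        for cx, cy in zip(px, py):
            x0, x1 = max(0, cx - r), min(w, cx + r + 1)
            y0, y1 = max(0, cy - r), min(h, cy + r + 1)
            grid[y0:y1, x0:x1] += kern[
                y0 - cy + r : y1 - cy + r, x0 - cx + r : x1 - cx + r
            ]
    return HeatMap(intensity=grid, saturation=saturation)


def alpha_coverage(heatmap: HeatMap) -> float:
    """Mean alpha of the map as a percentage of full coverage.

    ``100 * sum(alpha) / (255 * n_pixels)`` — 0 for an empty map, 100
    for a fully saturated one.
    """
    a = heatmap.alpha
    return 100.0 * float(a.sum()) / (255.0 * a.size)


def save_alpha_png(heatmap: HeatMap, path: str | Path) -> None:
    """Export the alpha layer as an 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(heatmap.alpha, mode="L").save(Path(path))


# ---------------------------------------------------------------------------
# quadrants


def quadrant_of(x: float, y: float, geometry: ScreenGeometry | None = None) -> str:
    """Label of the 3x3 screen cell containing the point.

    Rows A-C run top to bottom, columns 1-3 left to right; a point on an
    interior boundary belongs to the lower-indexed (upper/left) cell.
    Points outside the screen are clamped to the nearest cell.
    """
    geometry = geometry or ScreenGeometry()
    px, py = geometry.to_px(np.asarray(x, float), np.asarray(y, float))
    col = int(np.searchsorted([geometry.width_px / 3, 2 * geometry.width_px / 3], px, side="left"))
    row = int(np.searchsorted([geometry.height_px / 3, 2 * geometry.height_px / 3], py, side="left"))
    return f"{'ABC'[min(row, 2)]}{min(col, 2) + 1}"


def quadrant_stats(
    fixations: Sequence[Fixation], geometry: ScreenGeometry | None = None
) -> tuple[dict[str, int], dict[str, float]]:
    """Fixation count and mean duration (ms) per 3x3 quadrant.

    Each fixation is assigned to exactly one cell by its centroid, so
    the nine counts partition the total.  Empty cells report a mean
    duration of 0.
    """
    geometry = geometry or ScreenGeometry()
    counts = {q: 0 for q in QUADRANT_LABELS}
    sums = {q: 0.0 for q in QUADRANT_LABELS}
    for f in fixations:
        q = quadrant_of(f.x, f.y, geometry)
        counts[q] += 1
        sums[q] += f.duration
    means = {q: (sums[q] / counts[q] if counts[q] else 0.0) for q in QUADRANT_LABELS}
    return counts, means


# ---------------------------------------------------------------------------
# the 34-feature vector

FEATURE_NAMES: tuple[str, ...] = (
    ("classification", "global_alpha", "fix_total_count",
     "fix_avg_duration", "fix_max_duration", "fix_min_duration")
    + tuple(f"fix_count_{q}" for q in QUADRANT_LABELS)
    + tuple(f"fix_avgdur_{q}" for q in QUADRANT_LABELS)
    + tuple(f"time_level{i}" for i in range(1, 5))
    + ("total_time",)
    + tuple(f"correct_level{i}" for i in range(1, 5))
    + ("total_correct",)
)
assert len(FEATURE_NAMES) == 34


def assemble_features(
    level_records: Mapping[str, FixationRecord],
    cohort_row: Mapping,
    outlier: bool = False,
    geometry: ScreenGeometry | None = None,
    kernel_radius_px: int = 50,
) -> pd.Series:
    """Build the 34-entry feature vector for one participant.

    Parameters
    ----------
    level_records
        Fixation records keyed by level name (``Level1``..``Level4``).
        A missing level contributes no fixations.
    cohort_row
        The participant's row of the cohort table (per-level times in s
        and correct counts plus totals).
    outlier
        The participant-level outlier flag from the robust screening
        stage (encoded 1 = outlier, 0 = normal).

    Gaze metrics pool the four levels: duration statistics and quadrant
    statistics are over all fixations; global alpha is the mean alpha
    coverage of the four per-level heat maps.  If records carry a
    participant id in their metadata it must match the cohort row.
    """
    geometry = geometry or ScreenGeometry()
    uid = str(cohort_row["participant_id"])
    for rec in level_records.values():
        if rec.meta.user_id and rec.meta.user_id != uid:
            raise ValueError(
                f"fixation record for user {rec.meta.user_id!r} does not "
                f"match cohort participant {uid!r}"
            )
    all_fix: list[Fixation] = []
    coverages = []
    for level in LEVELS:
        rec = level_records.get(level)
        fx = rec.fixations if rec is not None else []
        all_fix.extend(fx)
        coverages.append(
            alpha_coverage(render_heatmap(fx, geometry, kernel_radius_px))
        )
    durations = np.array([f.duration for f in all_fix])
    counts, means = quadrant_stats(all_fix, geometry)
    values: dict[str, float] = {
        "classification": float(bool(outlier)),
        "global_alpha": float(np.mean(coverages)),
        "fix_total_count": float(len(all_fix)),
        "fix_avg_duration": float(durations.mean()) if len(durations) else 0.0,
        "fix_max_duration": float(durations.max()) if len(durations) else 0.0,
        "fix_min_duration": float(durations.min()) if len(durations) else 0.0,
    }
    for q in QUADRANT_LABELS:
        values[f"fix_count_{q}"] = float(counts[q])
    for q in QUADRANT_LABELS:
        values[f"fix_avgdur_{q}"] = float(means[q])
    for i in range(1, 5):
        values[f"time_level{i}"] = float(cohort_row[f"time_level{i}"])
    values["total_time"] = float(cohort_row["total_time"])
    for i in range(1, 5):
        values[f"correct_level{i}"] = float(cohort_row[f"correct_level{i}"])
    values["total_correct"] = float(cohort_row["total_correct"])
    vec = pd.Series([values[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES), name=uid)
    if abs(sum(values[f"time_level{i}"] for i in range(1, 5)) - values["total_time"]) > 0.05:
        raise ValueError("per-level times do not sum to total_time")
    if sum(values[f"fix_count_{q}"] for q in QUADRANT_LABELS) != values["fix_total_count"]:
        raise AssertionError("quadrant counts do not partition the fixation count")
    return vec


def features_frame(vectors: Sequence[pd.Series]) -> pd.DataFrame:
    """Stack per-participant feature vectors into a participants x 34 frame."""
    df = pd.DataFrame(list(vectors))
    df.index.name = "participant_id"
    return df[list(FEATURE_NAMES)]
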