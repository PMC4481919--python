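"""Velocity-threshold (I-VT) fixation filtering.

Raw binocular gaze streams are turned into fixation events by a
six-stage chain:

1. :func:`fill_gaps` — linear interpolation across short tracking
   losses (blinks, brief drop-outs) up to ``max_gap_ms``;
2. :func:`reduce_noise` — a low-pass filter realised as a centred
   moving average, never averaging across remaining gaps;
3. :func:`compute_velocities` — per-sample angular velocity (deg/s)
   over a centred time window, using the exact two-vector visual angle
   given the viewing distance;
4. :func:`classify_ivt` — threshold the velocity (below → fixation,
   at/above → saccade, missing → gap) and group consecutive equal
   labels into runs;
5. :func:`merge_fixations` — re-join fixations split by noise or
   filled blinks when both the time gap and the angular separation of
   their centroids are small;
6. :func:`discard_short_fixations` — drop events too short to reflect
   visual intake.

:func:`run_pipeline` applies the stages in order.  Default parameters
(75 ms max gap, 20 ms velocity window, 30 deg/s threshold, 75 ms /
0.5 deg merge limits, 100 ms minimum duration) follow standard I-VT
practice for remote trackers sampling around 30 Hz.

Boundary conventions, which the thresholds alone do not determine, are
fixed as: velocity **≥** threshold is a saccade; duration **≥** the
minimum is kept; gaps of span **≤** the maximum are filled; fixation
pairs with gap **≤** max-time and separation **≤** max-angle merge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Sequence

import numpy as np

from .gaze_io import (
    EyeSample,
    Fixation,
    FixationRecord,
    GazeSample,
    RawGazeRecord,
)

__all__ = [
    "ScreenGeometry",
    "FilterParams",
    "SampleLabel",
    "LabeledStream",
    "fill_gaps",
    "reduce_noise",
    "combine_eyes",
    "compute_velocities",
    "classify_ivt",
    "merge_fixations",
    "discard_short_fixations",
    "run_pipeline",
    "visual_angle_deg",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry and viewing distance.

    Defaults describe the study setup: a 19-inch 1280x1024 monitor
    (5:4, ~376x301 mm active area) viewed from ~600 mm with the remote
    tracker beneath it.  ``coordinate_unit`` declares the unit of the
    recorded gaze coordinates; the recordings analysed here use screen
    millimetres from the top-left corner.
    """

    width_px: int = 1280
    height_px: int = 1024
    width_mm: float = 376.0
    height_mm: float = 301.0
    eye_distance_mm: float = 600.0
    coordinate_unit: str = "mm"  # "px", "mm" or "normalized"

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm", "eye_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coordinate_unit not in ("px", "mm", "normalized"):
            raise ValueError("coordinate_unit must be 'px', 'mm' or 'normalized'")

    def to_mm(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Convert recorded coordinates to screen millimetres."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.coordinate_unit == "mm":
            return x, y
        if self.coordinate_unit == "px":
            return x * self.width_mm / self.width_px, y * self.height_mm / self.height_px
        return x * self.width_mm, y * self.height_mm

    def to_px(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Convert recorded coordinates to pixels."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.coordinate_unit == "px":
            return x, y
        if self.coordinate_unit == "mm":
            return x * self.width_px / self.width_mm, y * self.height_px / self.height_mm
        return x * self.width_px, y * self.height_px


@dataclass(frozen=True)
class FilterParams:
    """Tunable parameters of the six-stage filter (times in ms).

    ``noise_window_ms=None`` selects a 3-sample moving average, the
    narrowest symmetric window; at ~30 Hz a literal 20 ms velocity
    window holds fewer than two samples, in which case the window is
    widened symmetrically to the nearest flanking samples.
    """

    max_gap_ms: float = 75.0
    noise_window_ms: float | None = None
    velocity_window_ms: float = 20.0
    velocity_threshold_deg_s: float = 30.0
    merge_max_time_ms: float = 75.0
    merge_max_angle_deg: float = 0.5
    min_fixation_ms: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "max_gap_ms",
            "velocity_window_ms",
            "velocity_threshold_deg_s",
            "merge_max_time_ms",
            "merge_max_angle_deg",
            "min_fixation_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_window_ms is not None and self.noise_window_ms <= 0:
            raise ValueError("noise_window_ms must be positive")
        if self.min_fixation_ms < self.velocity_window_ms:
            raise ValueError("min_fixation_ms must be >= velocity_window_ms")


class SampleLabel(IntEnum):
    GAP = 0
    FIXATION = 1
    SACCADE = 2


@dataclass
class LabeledStream:
    """Cyclopean gaze time series with per-sample velocity and label.

    ``t_ms`` are sample times; ``x``/``y`` are the combined (two-eye
    averaged) gaze point in the recording unit, NaN where no eye was
    valid; ``velocity`` is angular speed in deg/s (NaN on gaps);
    ``label`` holds :class:`SampleLabel` codes.
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    velocity: np.ndarray | None = None
    label: np.ndarray | None = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.x) & np.isfinite(self.y)

    def __len__(self) -> int:
        return len(self.t_ms)


def visual_angle_deg(
    x0, y0, x1, y1, geometry: ScreenGeometry
) -> np.ndarray:
    """Visual angle (deg) subtended by the displacement between two
    on-screen points, for an eye at ``eye_distance_mm`` facing the screen.

    Uses the exact two-vector (chord) angle ``2*atan(d / 2D)`` rather
    than the small-angle shortcut ``d/D``.
    """
    x0mm, y0mm = geometry.to_mm(np.asarray(x0, float), np.asarray(y0, float))
    x1mm, y1mm = geometry.to_mm(np.asarray(x1, float), np.asarray(y1, float))
    d = np.hypot(x1mm - x0mm, y1mm - y0mm)
    return np.degrees(2.0 * np.arctan2(d, 2.0 * geometry.eye_distance_mm))


# ---------------------------------------------------------------------------
# stage 1: gap fill-in


def fill_gaps(
    samples: Sequence[GazeSample], max_gap_ms: float = 75.0
) -> list[GazeSample]:
    """Interpolate short runs of invalid samples, per eye.

    A run of consecutive invalid samples is filled by linear
    interpolation (per coordinate and per eye) between the flanking
    valid samples when the duration of missing data — the span between
    the flanking valid samples minus one nominal sampling interval — is
    at most ``max_gap_ms``; longer runs, attributable to behaviour
    rather than tracking loss, are left untouched, as are runs at the
    stream edges.  Interpolated samples get validity 0 and the
    interpolated pupil diameter.
    """
    if not samples:
        return []
    out = list(samples)
    t = np.array([s.timestamp_ms for s in samples])
    dt_nominal = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    for eye_name in ("left", "right"):
        valid = np.array([getattr(s, eye_name).is_valid for s in samples])
        i = 0
        n = len(samples)
        while i < n:
            if valid[i]:
                i += 1
                continue
            j = i
            while j < n and not valid[j]:
                j += 1
            # invalid run [i, j); flanks i-1 and j
            if i > 0 and j < n and (t[j] - t[i - 1]) - dt_nominal <= max_gap_ms:
                a = getattr(samples[i - 1], eye_name)
                b = getattr(samples[j], eye_name)
                for k in range(i, j):
                    w = (t[k] - t[i - 1]) / (t[j] - t[i - 1])
                    filled = EyeSample(
                        x=a.x + w * (b.x - a.x),
                        y=a.y + w * (b.y - a.y),
                        pupil_diam=a.pupil_diam + w * (b.pupil_diam - a.pupil_diam),
                        validity=0,
                    )
                    out[k] = replace(out[k], **{eye_name: filled})
            i = j
    return out


# ---------------------------------------------------------------------------
# eye combination


def combine_eyes(samples: Sequence[GazeSample]) -> LabeledStream:
    """Average the two eyes into one cyclopean gaze point per sample.

    Both eyes valid → mean of the two points; one valid → that eye;
    neither → NaN (a gap sample).
    """
    n = len(samples)
    t = np.empty(n)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    for i, s in enumerate(samples):
        t[i] = s.timestamp_ms
        lv, rv = s.left.is_valid, s.right.is_valid
        if lv and rv:
            x[i] = 0.5 * (s.left.x + s.right.x)
            y[i] = 0.5 * (s.left.y + s.right.y)
        elif lv:
            x[i], y[i] = s.left.x, s.left.y
        elif rv:
            x[i], y[i] = s.right.x, s.right.y
    return LabeledStream(t_ms=t, x=x, y=y)


# ---------------------------------------------------------------------------
# stage 2: noise reduction


def reduce_noise(
    stream: LabeledStream, noise_window_ms: float | None = None
) -> LabeledStream:
    """Smooth gaze coordinates with a centred moving average.

    With ``noise_window_ms=None`` each sample is averaged with its two
    immediate neighbours (a 3-sample window); otherwise all samples
    within ``noise_window_ms/2`` of the centre sample enter the mean.
    Gap samples stay NaN and smoothing windows are truncated at gaps so
    that positions are never averaged across a tracking loss.
    """
    n = len(stream)
    if n == 0:
        return stream
    t, x, y = stream.t_ms, stream.x, stream.y
    valid = stream.valid
    xs = x.copy()
    ys = y.copy()
    # contiguous valid segments: never average across a gap
    starts = np.flatnonzero(valid & ~np.roll(valid, 1))
    if valid[0]:
        starts = np.union1d(starts, [0])
    for s0 in starts:
        s1 = s0
        while s1 < n and valid[s1]:
            s1 += 1
        seg = slice(s0, s1)
        tx, xx, yy = t[seg], x[seg], y[seg]
        m = s1 - s0
        for i in range(m):
            if noise_window_ms is None:
                lo, hi = max(0, i - 1), min(m, i + 2)
            else:
                half = noise_window_ms / 2.0
                lo = int(np.searchsorted(tx, tx[i] - half, side="left"))
                hi = int(np.searchsorted(tx, tx[i] + half, side="right"))
            xs[s0 + i] = xx[lo:hi].mean()
            ys[s0 + i] = yy[lo:hi].mean()
    return LabeledStream(t_ms=t, x=xs, y=ys)


# ---------------------------------------------------------------------------
# stage 3: velocity


def compute_velocities(
    stream: LabeledStream,
    geometry: ScreenGeometry,
    velocity_window_ms: float = 20.0,
) -> LabeledStream:
    """Attach an angular velocity (deg/s) to every valid sample.

    For each sample, the window nominally spans ``velocity_window_ms``
    centred on the sample; the velocity is the visual angle between the
    gaze points at the window's two ends divided by their time
    difference.  When fewer than two valid samples fall inside the
    nominal window (always the case at ~30 Hz with the 20 ms default),
    the window widens symmetrically to the nearest valid flanking
    samples within the same gap-free segment.  Samples with no valid
    neighbour (isolated, or a stream of fewer than two valid samples)
    get NaN velocity and are treated as gaps downstream.
    """
    n = len(stream)
    vel = np.full(n, np.nan)
    if n == 0:
        return replace_stream(stream, velocity=vel)
    t, x, y = stream.t_ms, stream.x, stream.y
    valid = stream.valid
    half = velocity_window_ms / 2.0
    # contiguous valid segments
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        seg_t, seg_x, seg_y = t[i:j], x[i:j], y[i:j]
        m = j - i
        if m >= 2:
            for k in range(m):
                lo = int(np.searchsorted(seg_t, seg_t[k] - half, side="left"))
                hi = int(np.searchsorted(seg_t, seg_t[k] + half, side="right")) - 1
                if hi <= lo:  # widen to nearest flanking samples
                    lo = max(0, k - 1)
                    hi = min(m - 1, k + 1)
                if hi > lo:
                    ang = float(
                        visual_angle_deg(
                            seg_x[lo], seg_y[lo], seg_x[hi], seg_y[hi], geometry
                        )
                    )
                    dt_s = (seg_t[hi] - seg_t[lo]) / 1000.0
                    vel[i + k] = ang / dt_s
        i = j
    return replace_stream(stream, velocity=vel)


def replace_stream(stream: LabeledStream, **kw) -> LabeledStream:
    d = dict(
        t_ms=stream.t_ms, x=stream.x, y=stream.y,
        velocity=stream.velocity, label=stream.label,
    )
    d.update(kw)
    return LabeledStream(**d)


# ---------------------------------------------------------------------------
# stage 4: I-VT classification


def _edge_velocities(stream: LabeledStream, geometry: ScreenGeometry) -> np.ndarray:
    """Angular velocity (deg/s) of each consecutive-sample edge.

    Entry ``i`` is the velocity between samples ``i`` and ``i+1``; NaN
    where either endpoint is a gap sample.
    """
    n = len(stream)
    if n < 2:
        return np.empty(0)
    ang = visual_angle_deg(
        stream.x[:-1], stream.y[:-1], stream.x[1:], stream.y[1:], geometry
    )
    dt_s = np.diff(stream.t_ms) / 1000.0
    with np.errstate(invalid="ignore"):
        return np.asarray(ang) / dt_s


def classify_ivt(
    stream: LabeledStream,
    velocity_threshold_deg_s: float = 30.0,
    geometry: ScreenGeometry | None = None,
) -> tuple[LabeledStream, list[Fixation]]:
    """Label every sample and extract fixation runs.

    Velocity below the threshold → fixation; at or above → saccade;
    undefined (gap or isolated sample) → gap.  At ~30 Hz a saccade
    often starts and ends within one sampling interval, so a sample is
    classified on the **minimum of its two one-sided velocities**: a
    sample that is stationary relative to either neighbour belongs to
    a fixation, and only samples moving on both sides are saccadic.
    This keeps fixation boundaries sharp where a centred window would
    absorb the samples flanking every saccade.

    Consecutive equal labels form runs, with one refinement: a
    fixation run is split at any internal edge whose inter-sample
    velocity reaches the threshold (a sub-sample saccade leaves no
    saccadic sample behind, only a fast edge).  Each run is summarised
    by the mean of its sample positions and its time span; because a
    sample stands for the sampling interval around it, a run's span
    extends toward the midpoint of the gap to the neighbouring run,
    capped at one median sampling interval (half at stream edges) —
    the instants alone would understate every duration by a full
    interval at this rate.
    """
    if stream.velocity is None:
        raise ValueError("compute_velocities must run before classify_ivt")
    geometry = geometry or ScreenGeometry()
    n = len(stream)
    valid = stream.valid
    edge_v = _edge_velocities(stream, geometry)
    labels = np.full(n, int(SampleLabel.GAP), dtype=np.int8)
    for i in range(n):
        if not valid[i]:
            continue
        sides = []
        if i > 0 and valid[i - 1]:
            sides.append(edge_v[i - 1])
        if i < n - 1 and valid[i + 1]:
            sides.append(edge_v[i])
        if not sides:
            continue  # isolated valid sample: velocity undefined -> gap
        v = min(sides)
        labels[i] = (
            int(SampleLabel.FIXATION)
            if v < velocity_threshold_deg_s
            else int(SampleLabel.SACCADE)
        )
    out = replace_stream(stream, label=labels)

    # maximal fixation runs, split at internal fast edges
    runs: list[tuple[int, int]] = []  # [i, j) sample index ranges
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] == int(SampleLabel.FIXATION):
            k = i
            for e in range(i, j - 1):
                if edge_v[e] >= velocity_threshold_deg_s:
                    runs.append((k, e + 1))
                    k = e + 1
            runs.append((k, j))
        i = j

    t = stream.t_ms
    cap = float(np.median(np.diff(t))) if n > 1 else 0.0
    fixations: list[Fixation] = []
    for ridx, (i, j) in enumerate(runs):
        # extend to the midpoint of the gap to the neighbouring fixation
        # run (capped at one interval); half an interval at stream edges
        prev_end = runs[ridx - 1][1] - 1 if ridx > 0 else None
        next_start = runs[ridx + 1][0] if ridx + 1 < len(runs) else None
        left = (t[i] - t[prev_end]) / 2.0 if prev_end is not None else cap / 2.0
        right = (t[next_start] - t[j - 1]) / 2.0 if next_start is not None else cap / 2.0
        t0 = t[i] - min(left, cap)
        t1 = t[j - 1] + min(right, cap)
        if t1 > t0:
            fixations.append(
                Fixation(
                    start_time=float(t0),
                    end_time=float(t1),
                    duration=float(t1 - t0),
                    x=float(stream.x[i:j].mean()),
                    y=float(stream.y[i:j].mean()),
                )
            )
    return out, fixations


# ---------------------------------------------------------------------------
# stage 5: merge


def merge_fixations(
    fixations: Sequence[Fixation],
    geometry: ScreenGeometry,
    merge_max_time_ms: float = 75.0,
    merge_max_angle_deg: float = 0.5,
) -> list[Fixation]:
    """Merge adjacent fixations separated by a short, small saccade or a
    filled blink.

    A pair of time-adjacent fixations merges when the interval between
    them (start of the later minus end of the earlier) is at most
    ``merge_max_time_ms`` **and** the visual angle between their
    centroids is at most ``merge_max_angle_deg``.  Merging scans
    left-to-right and repeats until no pair merges (a fixed point, so
    the operation is idempotent).  A merged fixation spans the first
    start to the last end; its centroid is the duration-weighted mean.
    """
    runs = sorted(fixations, key=lambda f: f.start_time)
    changed = True
    while changed:
        changed = False
        out: list[Fixation] = []
        for f in runs:
            if out:
                prev = out[-1]
                gap = f.start_time - prev.end_time
                ang = float(visual_angle_deg(prev.x, prev.y, f.x, f.y, geometry))
                if gap <= merge_max_time_ms and ang <= merge_max_angle_deg:
                    w0, w1 = prev.duration, f.duration
                    out[-1] = Fixation(
                        start_time=prev.start_time,
                        end_time=f.end_time,
                        duration=f.end_time - prev.start_time,
                        x=(prev.x * w0 + f.x * w1) / (w0 + w1),
                        y=(prev.y * w0 + f.y * w1) / (w0 + w1),
                    )
                    changed = True
                    continue
            out.append(f)
        runs = out
    return runs


# ---------------------------------------------------------------------------
# stage 6: minimum duration


def discard_short_fixations(
    fixations: Sequence[Fixation], min_fixation_ms: float = 100.0
) -> list[Fixation]:
    """Drop fixations shorter than ``min_fixation_ms`` (≥ is kept)."""
    return [f for f in fixations if f.duration >= min_fixation_ms]


# ---------------------------------------------------------------------------
# full chain


def run_pipeline(
    raw: RawGazeRecord,
    params: FilterParams | None = None,
    geometry: ScreenGeometry | None = None,
    return_stream: bool = False,
):
    """Run the six-stage chain on a raw record.

    Returns a :class:`~gazelab.gaze_io.FixationRecord` (with the input's
    session metadata); with ``return_stream=True`` also returns the
    labelled sample stream for inspection.
    """
    params = params or FilterParams()
    geometry = geometry or ScreenGeometry()
    filled = fill_gaps(raw.samples, params.max_gap_ms)
    stream = combine_eyes(filled)
    stream = reduce_noise(stream, params.noise_window_ms)
    stream = compute_velocities(stream, geometry, params.velocity_window_ms)
    stream, fixations = classify_ivt(stream, params.velocity_threshold_deg_s, geometry)
    fixations = merge_fixations(
        fixations, geometry, params.merge_max_time_ms, params.merge_max_angle_deg
    )
    fixations = discard_short_fixations(fixations, params.min_fixation_ms)
    record = FixationRecord(meta=raw.meta, fixations=fixations)
    if return_stream:
        return record, stream
    return record
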