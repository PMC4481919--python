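"""Seeded synthetic gaze sessions and two-group cohorts with ground truth.

No public recordings exist for the puzzle assessment, so every stage
of the pipeline is exercised on simulated data whose statistical
structure mirrors the study conditions: a remote tracker sampling at
28-32 Hz with ~0.5 deg accuracy, four 50 s puzzle levels, and two
performance groups — *strong* performers with few fixations whose
count decreases over the levels, and *weak* performers with many more
fixations and 6-9 of 16 correct answers against the strong group's 15.

:func:`simulate_session` renders one alternating fixation/saccade
event sequence into a binocular sample stream with Gaussian angular
noise and blink gaps, returning the raw record together with the true
event sequence (:class:`SyntheticGroundTruth`).  Saccades are
constant-velocity traversals well above the 30 deg/s classification
threshold; blink gaps draw durations both below and above the 75 ms
gap-fill limit so both branches of the fill-in stage are exercised.

:func:`simulate_cohort` builds a full cohort: four sessions per
participant plus a performance table consistent with the group
membership.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .gaze_io import (
    CohortTable,
    EyeSample,
    GazeSample,
    RawGazeRecord,
    SessionMeta,
    LEVELS,
)
from .ivt_filter import ScreenGeometry

__all__ = [
    "SessionProfile",
    "CohortSpec",
    "GroupProfile",
    "SyntheticGroundTruth",
    "TrueFixation",
    "simulate_session",
    "simulate_cohort",
    "STRONG_PROFILE",
    "WEAK_PROFILE",
    "paper_like_cohort_spec",
]


@dataclass(frozen=True)
class TrueFixation:
    start_ms: float
    end_ms: float
    x: float
    y: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class SyntheticGroundTruth:
    """The true event sequence behind a simulated stream."""

    fixations: list[TrueFixation] = field(default_factory=list)
    gaps: list[tuple[float, float]] = field(default_factory=list)
    group: str = ""

    def planted_count(self, min_duration_ms: float = 0.0) -> int:
        return sum(1 for f in self.fixations if f.duration_ms >= min_duration_ms)


@dataclass(frozen=True)
class SessionProfile:
    """Generative parameters of one gaze session.

    Durations are log-normal around ``fixation_median_ms`` with
    log-scale ``fixation_sigma``; positions are uniform over the
    central screen with at least ``min_shift_deg`` between successive
    fixation targets (so planted events stay separable); coordinate
    noise is Gaussian with SD ``noise_sd_deg`` of visual angle (0.25
    by default, half the tracker's nominal 0.5 deg accuracy bound).
    Blinks arrive as a Poisson process at ``blink_rate_hz`` with
    uniform durations between the given limits, straddling the 75 ms
    gap-fill threshold.
    """

    sampling_rate_hz: float = 30.0
    fixation_median_ms: float = 200.0
    fixation_sigma: float = 0.35
    min_shift_deg: float = 3.0
    saccade_velocity_deg_s: float = 200.0
    noise_sd_deg: float = 0.25
    blink_rate_hz: float = 0.1
    blink_min_ms: float = 40.0
    blink_max_ms: float = 160.0
    margin_frac: float = 0.1

    def __post_init__(self) -> None:
        if not (28.0 <= self.sampling_rate_hz <= 32.0):
            raise ValueError("sampling_rate_hz must lie in [28, 32]")
        if self.fixation_median_ms <= 0:
            raise ValueError("fixation durations must be positive")


def _deg_to_mm(deg: float, geometry: ScreenGeometry) -> float:
    """Chord length on the screen subtending ``deg`` at the eye."""
    return 2.0 * geometry.eye_distance_mm * math.tan(math.radians(deg) / 2.0)


def _next_position(
    rng: np.random.Generator,
    prev: np.ndarray | None,
    geometry: ScreenGeometry,
    profile: SessionProfile,
) -> np.ndarray:
    """A fixation target uniform in the margin-inset screen, at least
    ``min_shift_deg`` of visual angle away from the previous target."""
    m = profile.margin_frac
    lo = np.array([geometry.width_mm * m, geometry.height_mm * m])
    hi = np.array([geometry.width_mm * (1 - m), geometry.height_mm * (1 - m)])
    min_mm = _deg_to_mm(profile.min_shift_deg, geometry)
    for _ in range(200):
        p = rng.uniform(lo, hi)
        if prev is None or float(np.hypot(*(p - prev))) >= min_mm:
            return p
    return p


def simulate_session(
    profile: SessionProfile | None = None,
    duration_s: float = 50.0,
    seed: int | np.random.SeedSequence = 0,
    geometry: ScreenGeometry | None = None,
    meta: SessionMeta | None = None,
    n_fixations: int | None = None,
) -> tuple[RawGazeRecord, SyntheticGroundTruth]:
    """Simulate one gaze session.

    The event timeline alternates fixations (log-normal durations at
    drawn targets) and constant-velocity saccades until ``duration_s``
    is covered — or, if ``n_fixations`` is given, until that many
    fixations have been planted, whichever the caller asked for.
    Samples are emitted at the profile rate; both eyes see the same
    true gaze point plus independent Gaussian noise.  Blink gaps mark
    both eyes invalid (validity 4, coordinates -1, the tracker's
    convention for untracked samples).
    """
    profile = profile or SessionProfile()
    geometry = geometry or ScreenGeometry()
    meta = meta or SessionMeta(user_id="sim", level="Level1")
    rng = np.random.default_rng(seed)

    # --- event timeline ------------------------------------------------
    mu = math.log(profile.fixation_median_ms)
    fixations: list[TrueFixation] = []
    segments: list[tuple[float, float, np.ndarray, np.ndarray]] = []  # t0, t1, p0, p1
    t = 0.0
    p = _next_position(rng, None, geometry, profile)

    def more() -> bool:
        if n_fixations is not None:
            return len(fixations) < n_fixations
        return t < duration_s * 1000.0

    while more():
        dur = float(rng.lognormal(mu, profile.fixation_sigma))
        fixations.append(TrueFixation(start_ms=t, end_ms=t + dur, x=p[0], y=p[1]))
        segments.append((t, t + dur, p, p))
        t += dur
        if more():
            q = _next_position(rng, p, geometry, profile)
            dist_mm = float(np.hypot(*(q - p)))
            ang = math.degrees(2.0 * math.atan2(dist_mm, 2.0 * geometry.eye_distance_mm))
            sac_ms = 1000.0 * ang / profile.saccade_velocity_deg_s
            segments.append((t, t + sac_ms, p, q))
            t += sac_ms
            p = q
    total_ms = t

    # --- blink gaps -----------------------------------------------------
    gaps: list[tuple[float, float]] = []
    bt = float(rng.exponential(1000.0 / profile.blink_rate_hz)) if profile.blink_rate_hz > 0 else math.inf
    while bt < total_ms:
        b_dur = float(rng.uniform(profile.blink_min_ms, profile.blink_max_ms))
        gaps.append((bt, min(bt + b_dur, total_ms)))
        bt += b_dur + float(rng.exponential(1000.0 / profile.blink_rate_hz))

    # --- sampling -------------------------------------------------------
    dt_ms = 1000.0 / profile.sampling_rate_hz
    times = np.arange(0.0, total_ms, dt_ms)
    seg_t0 = np.array([s[0] for s in segments])
    idx = np.clip(np.searchsorted(seg_t0, times, side="right") - 1, 0, len(segments) - 1)
    true_xy = np.empty((len(times), 2))
    for k, (ti, si) in enumerate(zip(times, idx)):
        t0, t1, p0, p1 = segments[si]
        w = 0.0 if t1 <= t0 else np.clip((ti - t0) / (t1 - t0), 0.0, 1.0)
        true_xy[k] = p0 + w * (np.asarray(p1) - np.asarray(p0))
    noise_mm = _deg_to_mm(profile.noise_sd_deg, geometry) if profile.noise_sd_deg > 0 else 0.0
    in_gap = np.zeros(len(times), dtype=bool)
    for g0, g1 in gaps:
        in_gap |= (times >= g0) & (times < g1)

    origin_us = 1_167_610_000_000_000  # epoch-like origin of the recording clock
    samples = []
    for k, ti in enumerate(times):
        ts_us = origin_us + ti * 1000.0
        if in_gap[k]:
            blank = EyeSample(x=-1.0, y=-1.0, pupil_diam=-1.0, validity=4)
            samples.append(GazeSample(timestamp_us=ts_us, left=blank, right=blank))
            continue
        eyes = []
        for _ in range(2):
            nx, ny = (rng.normal(0.0, noise_mm), rng.normal(0.0, noise_mm)) if noise_mm else (0.0, 0.0)
            eyes.append(
                EyeSample(
                    x=float(true_xy[k, 0] + nx),
                    y=float(true_xy[k, 1] + ny),
                    pupil_diam=float(3.0 + rng.normal(0.0, 0.05)),
                    validity=0,
                )
            )
        samples.append(GazeSample(timestamp_us=ts_us, left=eyes[0], right=eyes[1]))

    record = RawGazeRecord(meta=meta, samples=samples)
    truth = SyntheticGroundTruth(fixations=fixations, gaps=gaps)
    return record, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupProfile:
    """Per-group generative parameters across the four levels.

    ``fixation_count_means`` are the Poisson means of the per-level
    fixation counts; ``correct_prob`` the per-item success probability
    of the 4 items per level; times are clipped normals below the 50 s
    level cap.
    """

    name: str
    fixation_count_means: tuple[float, float, float, float]
    fixation_median_ms: float
    correct_prob: float
    time_mean_s: float
    time_sd_s: float


#: Strong performers: few fixations, decreasing with level familiarity,
#: near-ceiling accuracy (totals around 15/16).
STRONG_PROFILE = GroupProfile(
    name="strong",
    fixation_count_means=(100.0, 30.0, 47.0, 40.0),
    fixation_median_ms=160.0,
    correct_prob=0.93,
    time_mean_s=43.0,
    time_sd_s=5.0,
)

#: Weak performers: many fixations with no decreasing trend, totals 6-9.
WEAK_PROFILE = GroupProfile(
    name="weak",
    fixation_count_means=(110.0, 99.0, 110.0, 141.0),
    fixation_median_ms=180.0,
    correct_prob=0.45,
    time_mean_s=47.5,
    time_sd_s=2.0,
)


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a simulated cohort."""

    n_participants: int = 32
    weak_fraction: float = 0.25
    strong: GroupProfile = STRONG_PROFILE
    weak: GroupProfile = WEAK_PROFILE
    session: SessionProfile = SessionProfile()

    def __post_init__(self) -> None:
        if not (0.0 < self.weak_fraction < 1.0):
            raise ValueError("weak_fraction must be in (0, 1)")
        if self.n_participants < 2:
            raise ValueError("a cohort needs at least two participants")


def paper_like_cohort_spec(n_participants: int = 32) -> CohortSpec:
    """The default study-like cohort: 32 participants, a quarter weak."""
    return CohortSpec(n_participants=n_participants)


def simulate_cohort(
    spec: CohortSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    geometry: ScreenGeometry | None = None,
) -> tuple[dict[str, dict[str, RawGazeRecord]], CohortTable, dict[str, str], dict[str, dict[str, SyntheticGroundTruth]]]:
    """Simulate a full two-group cohort.

    Returns ``(records, cohort_table, labels, truths)`` where
    ``records[pid][level]`` is the raw gaze record of one session,
    ``cohort_table`` the performance table consistent with group
    membership, ``labels[pid]`` the true group name and
    ``truths[pid][level]`` the planted event sequence.
    """
    spec = spec or CohortSpec()
    geometry = geometry or ScreenGeometry()
    root = np.random.SeedSequence(seed if isinstance(seed, int) else seed.entropy)
    rng = np.random.default_rng(root.spawn(1)[0])
    n_weak = max(1, round(spec.n_participants * spec.weak_fraction))
    group_names = ["weak"] * n_weak + ["strong"] * (spec.n_participants - n_weak)
    rng.shuffle(group_names)

    records: dict[str, dict[str, RawGazeRecord]] = {}
    truths: dict[str, dict[str, SyntheticGroundTruth]] = {}
    labels: dict[str, str] = {}
    rows = []
    child_seeds = root.spawn(spec.n_participants)
    for p_idx, (group_name, pseed) in enumerate(zip(group_names, child_seeds)):
        pid = f"P{p_idx + 1:02d}"
        prof = spec.strong if group_name == "strong" else spec.weak
        prng = np.random.default_rng(pseed)
        labels[pid] = group_name
        records[pid] = {}
        truths[pid] = {}
        row: dict[str, float | str] = {"participant_id": pid}
        level_seeds = pseed.spawn(4)
        total_time = 0.0
        total_correct = 0
        for li, (level, lseed) in enumerate(zip(LEVELS, level_seeds)):
            n_fix = max(3, int(prng.poisson(prof.fixation_count_means[li])))
            session_profile = replace(
                spec.session, fixation_median_ms=prof.fixation_median_ms
            )
            meta = SessionMeta(
                user_id=pid, session_id=str(900 + p_idx), exercise_id="puzzle",
                level=level, mode="performance",
            )
            rec, truth = simulate_session(
                session_profile,
                seed=lseed,
                geometry=geometry,
                meta=meta,
                n_fixations=n_fix,
            )
            truth.group = group_name
            records[pid][level] = rec
            truths[pid][level] = truth
            t_s = float(np.clip(prng.normal(prof.time_mean_s, prof.time_sd_s), 15.0, 50.0))
            c = int(prng.binomial(4, prof.correct_prob))
            row[f"time_level{li + 1}"] = round(t_s, 2)
            row[f"correct_level{li + 1}"] = c
            total_time += round(t_s, 2)
            total_correct += c
        row["total_time"] = round(total_time, 2)
        row["total_correct"] = total_correct
        rows.append(row)
    columns = (
        ["participant_id"]
        + [c for i in range(1, 5) for c in (f"time_level{i}", f"correct_level{i}")]
        + ["total_time", "total_correct"]
    )
    table = CohortTable(pd.DataFrame(rows)[columns])
    return records, table, labels, truths
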