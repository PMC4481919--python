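"""Reading and writing gaze-session files.

Two XML dialects are supported, matching the recording system of the
puzzle-based attention assessment this package analyses:

* **raw gaze documents** — one ``<user>`` element wrapping an
  ``<exercise>`` with an ``<eyedata>`` block; each ``<timestamp>`` child
  carries one binocular sample (``left_eye`` / ``right_eye`` with
  ``x``, ``y``, ``pupil_diam`` and a ``validity`` code).
* **fixation documents** — the same envelope around a ``<fixationData>``
  block whose ``<fixation>`` children carry ``duration``, ``start_time``,
  ``end_time`` and a ``<position>``.

Raw timestamps are microseconds on an epoch-like origin; fixation times
are milliseconds.  Everything is converted to milliseconds internally.
Attribute values may contain stray whitespace (as produced by the
original logger); they are stripped before numeric parsing.

Per-participant performance tables (per-level completion times and
correct answers) are read from CSV via :func:`read_cohort_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterator
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

__all__ = [
    "SessionMeta",
    "EyeSample",
    "GazeSample",
    "RawGazeRecord",
    "Fixation",
    "FixationRecord",
    "CohortTable",
    "GazeParseError",
    "GazeSchemaError",
    "read_raw_gaze",
    "iter_raw_gaze",
    "write_raw_gaze",
    "read_fixations",
    "write_fixations",
    "read_cohort_table",
    "write_cohort_table",
    "COHORT_COLUMNS",
    "LEVELS",
]

#: Canonical level names of the four-level assessment.
LEVELS = ("Level1", "Level2", "Level3", "Level4")

#: Validity code meaning "the eye was tracked" in the supported dialect.
VALID_CODE = 0


class GazeParseError(ValueError):
    """Malformed XML or a value that cannot be parsed as a number."""


class GazeSchemaError(ValueError):
    """Structurally valid XML that is missing a required element/attribute."""


@dataclass(frozen=True)
class SessionMeta:
    """Identifying attributes of one recorded exercise session."""

    user_id: str
    session_id: str = ""
    date: str = ""
    time: str = ""
    exercise_id: str = "puzzle"
    level: str = "Level1"
    mode: str = "performance"

    def __post_init__(self) -> None:
        if not self.user_id:
            raise ValueError("user_id must be non-empty")
        if not self.level:
            raise ValueError("level must be non-empty")


@dataclass(frozen=True)
class EyeSample:
    """One eye's measurement in a single sample.

    ``x``/``y`` are stored verbatim in the recording's screen coordinate
    unit (configurable downstream; see ``ScreenGeometry``).  ``pupil_diam``
    is millimetres.  A sample is usable only when ``validity`` equals the
    tracker's "tracked" code (0 here) and the coordinates are finite.
    """

    x: float
    y: float
    pupil_diam: float
    validity: int

    @property
    def is_valid(self) -> bool:
        return (
            self.validity == VALID_CODE
            and math.isfinite(self.x)
            and math.isfinite(self.y)
        )


@dataclass(frozen=True)
class GazeSample:
    """One timestamped binocular gaze measurement (timestamp in µs)."""

    timestamp_us: float
    left: EyeSample
    right: EyeSample

    @property
    def timestamp_ms(self) -> float:
        return self.timestamp_us / 1000.0


@dataclass
class RawGazeRecord:
    """A raw gaze stream for one participant and exercise level."""

    meta: SessionMeta
    samples: list[GazeSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = [s.timestamp_us for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("samples must be strictly increasing in time")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Fixation:
    """A detected stable-gaze event.  Times in ms, position in screen units."""

    start_time: float
    end_time: float
    duration: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")
        # recorded files print start/end at coarser precision than the
        # duration attribute, so allow a few ms of rounding slack
        if abs((self.end_time - self.start_time) - self.duration) > 5.0:
            raise ValueError(
                "duration inconsistent with start/end times "
                f"({self.end_time - self.start_time:.3f} vs {self.duration:.3f})"
            )


@dataclass
class FixationRecord:
    """Ordered, non-overlapping fixations for one session."""

    meta: SessionMeta
    fixations: list[Fixation] = field(default_factory=list)

    def __post_init__(self) -> None:
        fx = self.fixations
        for a, b in zip(fx, fx[1:]):
            if b.start_time < a.start_time:
                raise ValueError("fixations must be sorted by start_time")
            if b.start_time < a.end_time - 0.5:
                raise ValueError("fixations must not overlap")

    def __len__(self) -> int:
        return len(self.fixations)

    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self.fixations], dtype=float)


# ---------------------------------------------------------------------------
# raw gaze XML


def _num(element: ET.Element, attr: str) -> float:
    """Parse a numeric attribute, tolerating embedded whitespace."""
    raw = element.get(attr)
    if raw is None:
        raise GazeSchemaError(
            f"<{element.tag}> is missing required attribute {attr!r}"
        )
    try:
        return float(raw.replace(" ", ""))
    except ValueError as exc:
        raise GazeParseError(
            f"attribute {attr}={raw!r} of <{element.tag}> is not numeric"
        ) from exc


def _text(element: ET.Element, attr: str, default: str | None = None) -> str:
    raw = element.get(attr)
    if raw is None:
        if default is not None:
            return default
        raise GazeSchemaError(
            f"<{element.tag}> is missing required attribute {attr!r}"
        )
    return raw.strip()


def _parse_root(source: str | Path | IO) -> ET.Element:
    try:
        if isinstance(source, (str, Path)) and not str(source).lstrip().startswith("<"):
            return ET.parse(source).getroot()
        if isinstance(source, str):
            return ET.fromstring(source)
        return ET.parse(source).getroot()
    except ET.ParseError as exc:
        raise GazeParseError(f"malformed XML document: {exc}") from exc


def _meta_from(user: ET.Element, exercise: ET.Element) -> SessionMeta:
    return SessionMeta(
        user_id=_text(user, "id"),
        session_id=_text(user, "sessionid", ""),
        date=_text(user, "date", ""),
        time=_text(user, "time", ""),
        exercise_id=_text(exercise, "id"),
        level=_text(exercise, "level"),
        mode=_text(exercise, "mode", ""),
    )


def _parse_eye(timestamp_el: ET.Element, tag: str) -> EyeSample:
    eye = timestamp_el.find(tag)
    if eye is None:
        raise GazeSchemaError(f"<timestamp> is missing a <{tag}> child")
    return EyeSample(
        x=_num(eye, "x"),
        y=_num(eye, "y"),
        pupil_diam=_num(eye, "pupil_diam"),
        validity=int(_num(eye, "validity")),
    )


def iter_raw_gaze(source: str | Path | IO) -> Iterator[RawGazeRecord]:
    """Yield one :class:`RawGazeRecord` per ``<exercise>`` element."""
    root = _parse_root(source)
    users = [root] if root.tag == "user" else root.findall(".//user")
    if not users:
        raise GazeSchemaError("document contains no <user> element")
    for user in users:
        exercises = user.findall("exercise")
        if not exercises:
            raise GazeSchemaError("<user> contains no <exercise> element")
        for exercise in exercises:
            eyedata = exercise.find("eyedata")
            if eyedata is None:
                raise GazeSchemaError("<exercise> contains no <eyedata> element")
            samples = [
                GazeSample(
                    timestamp_us=_num(ts, "time"),
                    left=_parse_eye(ts, "left_eye"),
                    right=_parse_eye(ts, "right_eye"),
                )
                for ts in eyedata.findall("timestamp")
            ]
            yield RawGazeRecord(meta=_meta_from(user, exercise), samples=samples)


def read_raw_gaze(source: str | Path | IO) -> RawGazeRecord:
    """Read a single-session raw gaze document.

    Raises :class:`GazeSchemaError` if the document holds more than one
    exercise; use :func:`iter_raw_gaze` for multi-session documents.
    """
    records = list(iter_raw_gaze(source))
    if len(records) != 1:
        raise GazeSchemaError(
            f"expected exactly one exercise session, found {len(records)}"
        )
    return records[0]


def _user_element(meta: SessionMeta) -> tuple[ET.Element, ET.Element]:
    user = ET.Element(
        "user",
        {
            "date": meta.date,
            "id": meta.user_id,
            "sessionid": meta.session_id,
            "time": meta.time,
        },
    )
    exercise = ET.SubElement(
        user, "exercise", {"id": meta.exercise_id, "level": meta.level, "mode": meta.mode}
    )
    return user, exercise


def write_raw_gaze(record: RawGazeRecord, path: str | Path | None = None) -> str:
    """Serialize a raw gaze record to the Listing-style XML dialect."""
    user, exercise = _user_element(record.meta)
    eyedata = ET.SubElement(exercise, "eyedata")
    for s in record.samples:
        ts = ET.SubElement(eyedata, "timestamp", {"time": repr(float(s.timestamp_us))})
        for tag, eye in (("left_eye", s.left), ("right_eye", s.right)):
            ET.SubElement(
                ts,
                tag,
                {
                    "pupil_diam": repr(float(eye.pupil_diam)),
                    "validity": str(eye.validity),
                    "x": repr(float(eye.x)),
                    "y": repr(float(eye.y)),
                },
            )
    ET.indent(user)
    text = ET.tostring(user, encoding="unicode")
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# fixation XML


def read_fixations(source: str | Path | IO) -> FixationRecord:
    """Read a fixation document (inverse of :func:`write_fixations`)."""
    root = _parse_root(source)
    user = root if root.tag == "user" else root.find(".//user")
    if user is None:
        raise GazeSchemaError("document contains no <user> element")
    exercise = user.find("exercise")
    if exercise is None:
        raise GazeSchemaError("<user> contains no <exercise> element")
    fixdata = exercise.find("fixationData")
    if fixdata is None:
        raise GazeSchemaError("<exercise> contains no <fixationData> element")
    fixations = []
    for fx in fixdata.findall("fixation"):
        time_el = fx.find("time")
        if time_el is None:
            raise GazeSchemaError("<fixation> contains no <time> element")
        pos = time_el.find("position")
        if pos is None:
            raise GazeSchemaError("<time> contains no <position> element")
        fixations.append(
            Fixation(
                start_time=_num(time_el, "start_time"),
                end_time=_num(time_el, "end_time"),
                duration=_num(time_el, "duration"),
                x=_num(pos, "x"),
                y=_num(pos, "y"),
            )
        )
    return FixationRecord(meta=_meta_from(user, exercise), fixations=fixations)


def write_fixations(record: FixationRecord, path: str | Path | None = None) -> str:
    """Serialize a fixation record; ``read_fixations`` round-trips it."""
    user, exercise = _user_element(record.meta)
    fixdata = ET.SubElement(exercise, "fixationData")
    for f in record.fixations:
        fx = ET.SubElement(fixdata, "fixation")
        time_el = ET.SubElement(
            fx,
            "time",
            {
                "duration": repr(float(f.duration)),
                "end_time": repr(float(f.end_time)),
                "start_time": repr(float(f.start_time)),
            },
        )
        ET.SubElement(time_el, "position", {"x": repr(float(f.x)), "y": repr(float(f.y))})
    ET.indent(user)
    text = ET.tostring(user, encoding="unicode")
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# cohort performance tables

#: Required columns of a cohort CSV, in canonical order.
COHORT_COLUMNS = (
    ["participant_id"]
    + [c for i in range(1, 5) for c in (f"time_level{i}", f"correct_level{i}")]
    + ["total_time", "total_correct"]
)

#: Per-level completion-time cap of the assessment, seconds.
LEVEL_TIME_CAP_S = 50.0

#: Correct answers available per level.
MAX_CORRECT_PER_LEVEL = 4


@dataclass
class CohortTable:
    """Per-participant, per-level completion times and correct answers.

    Wraps a :class:`pandas.DataFrame` with the :data:`COHORT_COLUMNS`
    schema (optional ``age`` / ``gender`` columns are preserved).  On
    construction the stored totals are checked against the per-level
    values: correct answers must sum exactly; times must agree to 0.05 s
    (the source tables are printed to two decimals, so row totals can
    disagree with column sums by a few hundredths).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise GazeSchemaError(f"cohort table is missing columns: {missing}")
        df = self.data
        correct_cols = [f"correct_level{i}" for i in range(1, 5)]
        time_cols = [f"time_level{i}" for i in range(1, 5)]
        bad = df.loc[df[correct_cols].sum(axis=1) != df["total_correct"]]
        if len(bad):
            ids = ", ".join(map(str, bad["participant_id"]))
            raise ValueError(f"total_correct != sum of levels for participants: {ids}")
        bad = df.loc[(df[time_cols].sum(axis=1) - df["total_time"]).abs() > 0.05]
        if len(bad):
            ids = ", ".join(map(str, bad["participant_id"]))
            raise ValueError(f"total_time != sum of levels for participants: {ids}")
        if (df[time_cols].to_numpy() > LEVEL_TIME_CAP_S).any():
            raise ValueError(f"per-level time exceeds the {LEVEL_TIME_CAP_S:.0f} s cap")
        if (df[correct_cols].to_numpy() > MAX_CORRECT_PER_LEVEL).any():
            raise ValueError("per-level correct count exceeds the 4 available items")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def participant_ids(self) -> list:
        return list(self.data["participant_id"])

    def row(self, participant_id) -> pd.Series:
        sel = self.data.loc[self.data["participant_id"] == participant_id]
        if not len(sel):
            raise KeyError(f"no participant {participant_id!r} in cohort table")
        return sel.iloc[0]


def read_cohort_table(source: str | Path | IO) -> CohortTable:
    """Read a cohort performance CSV and validate its consistency."""
    return CohortTable(pd.read_csv(source))


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)
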