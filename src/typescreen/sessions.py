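"""Data model and readers/writers for raw touchscreen typing sessions.

A *typing session* is every keystroke between one keyboard launch and its
subsequent close.  Each key event carries press/release timestamps in epoch
milliseconds and, unless the session was captured in privacy mode, the pixel
coordinates of the key on the (portrait-orientation) screen.  In privacy mode
only the inter-key Euclidean distances (millimetres) are retained, so the
identity of the keys pressed can never be reconstructed.

Two on-disk formats are supported: JSON Lines (one session per line, the
canonical format) and a flat CSV with one event per row.  Cohort metadata
(PHQ-9 item responses and demographics) travels in a separate CSV.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

MM_PER_INCH = 25.4

__all__ = [
    "KeyEvent",
    "RawTypingSession",
    "Subject",
    "SchemaError",
    "SessionValidationError",
    "read_sessions",
    "write_sessions",
    "read_cohort_metadata",
    "write_cohort_metadata",
    "compute_event_distances",
]


class SchemaError(ValueError):
    """A required field is missing or malformed in an input file."""


class SessionValidationError(ValueError):
    """A session violates a structural invariant (e.g. non-monotone presses)."""


@dataclass(frozen=True)
class KeyEvent:
    """One key press/release pair.

    Timestamps are epoch milliseconds; coordinates are portrait-orientation
    pixels (origin top-left, x rightward, y downward) or ``None`` in privacy
    mode.
    """

    press_time: int
    release_time: int
    x: float | None = None
    y: float | None = None
    is_delete: bool = False

    def __post_init__(self) -> None:
        if self.release_time < self.press_time:
            raise SessionValidationError(
                f"release_time {self.release_time} precedes press_time {self.press_time}"
            )
        for name, v in (("x", self.x), ("y", self.y)):
            if v is not None and v < 0:
                raise SessionValidationError(f"negative coordinate {name}={v}")


@dataclass
class RawTypingSession:
    """Ordered key events of one keyboard launch-to-close interaction.

    Exactly one of {per-event coordinates, ``distances_mm``} must be present.
    Press timestamps are strictly increasing, and so are releases; a release
    may interleave with later presses (two-handed overlap), which is why
    negative flight times are legal in raw data.
    """

    subject_id: str
    session_id: str
    start_time: int
    events: list[KeyEvent]
    screen_density_x: float
    screen_density_y: float
    app_name: str | None = None
    distances_mm: list[float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_keys(self) -> int:
        return len(self.events)

    @property
    def has_coordinates(self) -> bool:
        return any(e.x is not None for e in self.events)

    def validate(self) -> None:
        if self.screen_density_x <= 0 or self.screen_density_y <= 0:
            raise SessionValidationError(
                f"session {self.session_id}: screen densities must be positive"
            )
        presses = [e.press_time for e in self.events]
        releases = [e.release_time for e in self.events]
        if any(b <= a for a, b in zip(presses, presses[1:])):
            raise SessionValidationError(
                f"session {self.session_id}: press timestamps not strictly increasing"
            )
        if any(b <= a for a, b in zip(releases, releases[1:])):
            raise SessionValidationError(
                f"session {self.session_id}: release timestamps not strictly increasing"
            )
        has_xy = self.has_coordinates
        if has_xy and self.distances_mm is not None:
            raise SessionValidationError(
                f"session {self.session_id}: both coordinates and distances_mm present"
            )
        if not has_xy and self.distances_mm is None and len(self.events) > 1:
            raise SessionValidationError(
                f"session {self.session_id}: neither coordinates nor distances_mm present"
            )
        if self.distances_mm is not None and len(self.distances_mm) != max(
            len(self.events) - 1, 0
        ):
            raise SessionValidationError(
                f"session {self.session_id}: distances_mm length "
                f"{len(self.distances_mm)} != n_events - 1 = {len(self.events) - 1}"
            )


@dataclass
class Subject:
    """A study participant: PHQ-9 responses, demographics and their sessions."""

    subject_id: str
    phq9_items: list[int] | None = None
    phq9_score: int | None = None
    age: float | None = None
    gender: str | None = None
    education: str | None = None
    sessions: list[RawTypingSession] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phq9_items is not None:
            if len(self.phq9_items) != 9 or any(
                not (0 <= it <= 3) for it in self.phq9_items
            ):
                raise SchemaError(
                    f"subject {self.subject_id}: PHQ-9 items must be 9 integers in [0, 3]"
                )
            total = sum(self.phq9_items)
            if self.phq9_score is None:
                self.phq9_score = total
            elif self.phq9_score != total:
                raise SchemaError(
                    f"subject {self.subject_id}: phq9_score {self.phq9_score} != "
                    f"sum of items {total}"
                )


def compute_event_distances(session: RawTypingSession) -> list[float]:
    """Euclidean distances (mm) between consecutive key coordinates.

    Pixel offsets are converted through the per-axis screen densities
    (pixels per inch), i.e. ``d = sqrt((dx/ppi_x * 25.4)^2 + (dy/ppi_y * 25.4)^2)``.
    """
    if session.distances_mm is not None:
        return list(session.distances_mm)
    dx_scale = MM_PER_INCH / session.screen_density_x
    dy_scale = MM_PER_INCH / session.screen_density_y
    out: list[float] = []
    for a, b in zip(session.events, session.events[1:]):
        if a.x is None or b.x is None or a.y is None or b.y is None:
            raise SessionValidationError(
                f"session {session.session_id}: event lacks coordinates"
            )
        out.append(math.hypot((b.x - a.x) * dx_scale, (b.y - a.y) * dy_scale))
    return out


# ---------------------------------------------------------------------------
# JSONL
# ---------------------------------------------------------------------------

_REQUIRED_SESSION_FIELDS = (
    "subject_id",
    "session_id",
    "start_time",
    "screen_density_x",
    "screen_density_y",
    "events",
)


def _session_to_record(session: RawTypingSession, privacy: bool) -> dict:
    if privacy and session.has_coordinates:
        distances = compute_event_distances(session)
        events = [
            {"p": e.press_time, "r": e.release_time, "x": None, "y": None,
             "del": e.is_delete}
            for e in session.events
        ]
    else:
        distances = session.distances_mm
        events = [
            {"p": e.press_time, "r": e.release_time, "x": e.x, "y": e.y,
             "del": e.is_delete}
            for e in session.events
        ]
    return {
        "subject_id": session.subject_id,
        "session_id": session.session_id,
        "start_time": session.start_time,
        "app_name": session.app_name,
        "screen_density_x": session.screen_density_x,
        "screen_density_y": session.screen_density_y,
        "events": events,
        "distances_mm": distances,
    }


def _record_to_session(rec: dict, line_no: int) -> RawTypingSession:
    for f in _REQUIRED_SESSION_FIELDS:
        if f not in rec:
            raise SchemaError(f"line {line_no}: missing required field '{f}'")
    events = []
    for ev in rec["events"]:
        for f in ("p", "r"):
            if f not in ev:
                raise SchemaError(f"line {line_no}: event missing field '{f}'")
        events.append(
            KeyEvent(
                press_time=int(ev["p"]),
                release_time=int(ev["r"]),
                x=ev.get("x"),
                y=ev.get("y"),
                is_delete=bool(ev.get("del", False)),
            )
        )
    events.sort(key=lambda e: e.press_time)
    return RawTypingSession(
        subject_id=str(rec["subject_id"]),
        session_id=str(rec["session_id"]),
        start_time=int(rec["start_time"]),
        app_name=rec.get("app_name"),
        screen_density_x=float(rec["screen_density_x"]),
        screen_density_y=float(rec["screen_density_y"]),
        events=events,
        distances_mm=rec.get("distances_mm"),
    )


def read_sessions(
    path: str | Path, format: str | None = None, strict: bool = False
) -> list[RawTypingSession]:
    """Read typing sessions from a JSONL or CSV file.

    Sessions are returned grouped by subject and ordered by start time within
    each subject.  Malformed rows are rejected and counted (logged) unless
    ``strict`` is true, in which case the first offending row raises.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        sessions = _read_jsonl(path, strict)
    elif format == "csv":
        sessions = _read_csv(path, strict)
    else:
        raise ValueError(f"unknown session format: {format!r}")
    sessions.sort(key=lambda s: (s.subject_id, s.start_time, s.session_id))
    return sessions


def _read_jsonl(path: Path, strict: bool) -> list[RawTypingSession]:
    sessions: list[RawTypingSession] = []
    rejected = 0
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                sessions.append(_record_to_session(rec, i))
            except (SchemaError, SessionValidationError, json.JSONDecodeError) as exc:
                if strict:
                    raise
                rejected += 1
                logger.warning("rejected session at line %d: %s", i, exc)
    if rejected:
        logger.info("read %d sessions, rejected %d malformed rows", len(sessions), rejected)
    return sessions


# ---------------------------------------------------------------------------
# CSV (one event per row)
# ---------------------------------------------------------------------------

_CSV_HEADER = [
    "subject_id", "session_id", "start_time",
    "press_ms", "release_ms", "x", "y", "is_delete",
]


def _read_csv(path: Path, strict: bool) -> list[RawTypingSession]:
    groups: dict[tuple[str, str], dict] = {}
    rejected = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            try:
                key = (row["subject_id"], row["session_id"])
                g = groups.setdefault(
                    key,
                    {"start_time": int(row["start_time"]), "events": [],
                     "density": (400.0, 400.0)},
                )
                x = row.get("x") or None
                y = row.get("y") or None
                g["events"].append(
                    KeyEvent(
                        press_time=int(row["press_ms"]),
                        release_time=int(row["release_ms"]),
                        x=float(x) if x is not None else None,
                        y=float(y) if y is not None else None,
                        is_delete=row.get("is_delete", "").strip().lower()
                        in ("1", "true", "yes"),
                    )
                )
                if "density_x" in row and row["density_x"]:
                    g["density"] = (float(row["density_x"]), float(row["density_y"]))
            except (KeyError, TypeError, ValueError) as exc:
                if strict:
                    raise SchemaError(f"line {i}: {exc}") from exc
                rejected += 1
                logger.warning("rejected CSV event at line %d: %s", i, exc)
    sessions = []
    for (sid, sess_id), g in groups.items():
        events = sorted(g["events"], key=lambda e: e.press_time)
        sessions.append(
            RawTypingSession(
                subject_id=sid,
                session_id=sess_id,
                start_time=g["start_time"],
                events=events,
                screen_density_x=g["density"][0],
                screen_density_y=g["density"][1],
            )
        )
    if rejected:
        logger.info("read %d sessions, rejected %d malformed rows", len(sessions), rejected)
    return sessions


def write_sessions(
    sessions: Sequence[RawTypingSession],
    path: str | Path,
    privacy: bool = False,
    format: str | None = None,
) -> None:
    """Write sessions to JSONL (canonical) or CSV.

    With ``privacy=True`` coordinates are replaced by locally computed
    inter-key distances so key identity cannot be reconstructed downstream.
    CSV output does not support privacy mode (it has no distance column).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for s in sessions:
                fh.write(json.dumps(_session_to_record(s, privacy)) + "\n")
    elif format == "csv":
        if privacy:
            raise ValueError("privacy mode requires the JSONL format")
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER + ["density_x", "density_y"])
            for s in sessions:
                for e in s.events:
                    writer.writerow(
                        [s.subject_id, s.session_id, s.start_time,
                         e.press_time, e.release_time,
                         "" if e.x is None else e.x,
                         "" if e.y is None else e.y,
                         int(e.is_delete),
                         s.screen_density_x, s.screen_density_y]
                    )
    else:
        raise ValueError(f"unknown session format: {format!r}")


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------

def read_cohort_metadata(path: str | Path) -> list[Subject]:
    """Read the cohort metadata CSV: subject_id,phq1..phq9,age,gender,education."""
    subjects = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            try:
                items = [int(row[f"phq{j}"]) for j in range(1, 10)]
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"line {i}: bad PHQ-9 items ({exc})") from exc
            subjects.append(
                Subject(
                    subject_id=row["subject_id"],
                    phq9_items=items,
                    age=float(row["age"]) if row.get("age") else None,
                    gender=row.get("gender") or None,
                    education=row.get("education") or None,
                )
            )
    return subjects


def write_cohort_metadata(subjects: Iterable[Subject], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["subject_id"] + [f"phq{j}" for j in range(1, 10)]
            + ["age", "gender", "education"]
        )
        for s in subjects:
            items = s.phq9_items if s.phq9_items is not None else [""] * 9
            writer.writerow(
                [s.subject_id, *items,
                 "" if s.age is None else s.age,
                 s.gender or "", s.education or ""]
            )
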