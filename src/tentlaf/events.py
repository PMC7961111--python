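"""Domain types and readers/writers for annotated gaze/action event streams.

One participant's record is an :class:`EventLog`: time-ordered subtask
intervals, object-labeled fixation events, and touch events, all in float
seconds from trial start (annotations made at 30 Hz convert as frame/30).
Subtask intervals are half-open ``[t_start, t_end)`` so abutting intervals
tile time without double counting; gaps between intervals are approach time.

The on-disk format is a single events CSV, one row per event::

    participant,stream,label,t_start,t_end

with ``stream`` one of ``subtask``, ``fixation``, ``touch``.  Touch rows use
``t_start == t_end``.  Fixation rows with an empty label are off-object
fixations (gaze elsewhere).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .vocab import (
    APPROACH,
    VocabularyError,
    canonical_object,
    canonical_subtask,
)

__all__ = [
    "FixationEvent",
    "TouchEvent",
    "SubtaskInterval",
    "EventLog",
    "ParseError",
    "ValidationError",
    "read_event_log",
    "read_event_logs",
    "write_event_logs",
    "ongoing_subtask_at",
    "subtask_sequence",
    "non_approach_intervals",
]

STREAMS = ("subtask", "fixation", "touch")


class ParseError(ValueError):
    """Malformed events-CSV row; the message names the offending line."""


class ValidationError(ValueError):
    """Event streams violate an EventLog invariant (overlap, ordering...)."""


@dataclass(frozen=True)
class FixationEvent:
    participant: str
    t_start: float
    t_end: float
    target: str | None  # canonical object label, or None for off-object

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class TouchEvent:
    participant: str
    t: float
    object: str  # canonical object label


@dataclass(frozen=True)
class SubtaskInterval:
    participant: str
    label: str  # canonical subtask label (may be "approach" if annotated)
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class EventLog:
    """One participant's validated, time-sorted event streams."""

    participant: str
    fixations: list[FixationEvent] = field(default_factory=list)
    touches: list[TouchEvent] = field(default_factory=list)
    subtasks: list[SubtaskInterval] = field(default_factory=list)
    trial_duration: float = 0.0

    def __post_init__(self) -> None:
        self.fixations = sorted(self.fixations, key=lambda f: f.t_start)
        self.touches = sorted(self.touches, key=lambda t: t.t)
        self.subtasks = sorted(self.subtasks, key=lambda s: s.t_start)
        last = self._max_event_time()
        if self.trial_duration <= 0.0:
            self.trial_duration = last
        self.validate()

    def _max_event_time(self) -> float:
        times = [f.t_end for f in self.fixations]
        times += [t.t for t in self.touches]
        times += [s.t_end for s in self.subtasks]
        return max(times, default=0.0)

    def validate(self) -> None:
        p = self.participant
        for ev in (*self.fixations, *self.touches, *self.subtasks):
            if ev.participant != p:
                raise ValidationError(
                    f"event for {ev.participant!r} in log of {p!r}"
                )
        for f in self.fixations:
            if not f.t_end > f.t_start:
                raise ValidationError(
                    f"fixation with t_end <= t_start at t={f.t_start} ({p})"
                )
            if f.t_start < 0:
                raise ValidationError(f"negative fixation time ({p})")
        for a, b in zip(self.fixations, self.fixations[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValidationError(
                    f"overlapping fixations at t={b.t_start:g} ({p})"
                )
        for t in self.touches:
            if t.t < 0:
                raise ValidationError(f"negative touch time ({p})")
        for s in self.subtasks:
            if not s.t_end > s.t_start:
                raise ValidationError(
                    f"subtask interval with t_end <= t_start at t={s.t_start} ({p})"
                )
            if s.t_start < 0:
                raise ValidationError(f"negative subtask time ({p})")
        for a, b in zip(self.subtasks, self.subtasks[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValidationError(
                    f"overlapping subtask intervals "
                    f"[{a.t_start:g},{a.t_end:g}) and [{b.t_start:g},{b.t_end:g}) ({p})"
                )
        if self.trial_duration + 1e-9 < self._max_event_time():
            raise ValidationError(f"trial_duration shorter than event span ({p})")


def _parse_rows(df: pd.DataFrame, path: str) -> dict[str, dict[str, list]]:
    required = ["participant", "stream", "label", "t_start", "t_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    by_participant: dict[str, dict[str, list]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        pid = str(row.participant)
        stream = str(row.stream).strip().lower()
        if stream not in STREAMS:
            raise ParseError(f"{path}:{line}: unknown stream {row.stream!r}")
        try:
            t0 = float(row.t_start)
            t1 = float(row.t_end)
        except (TypeError, ValueError):
            raise ParseError(f"{path}:{line}: non-numeric time") from None
        if math.isnan(t0) or math.isnan(t1):
            raise ParseError(f"{path}:{line}: missing time value")
        raw_label = "" if pd.isna(row.label) else str(row.label).strip()
        streams = by_participant.setdefault(
            pid, {"fixation": [], "touch": [], "subtask": []}
        )
        try:
            if stream == "fixation":
                target = canonical_object(raw_label) if raw_label else None
                streams["fixation"].append(FixationEvent(pid, t0, t1, target))
            elif stream == "touch":
                if abs(t1 - t0) > 1e-9:
                    raise ParseError(
                        f"{path}:{line}: touch row must have t_start == t_end"
                    )
                streams["touch"].append(TouchEvent(pid, t0, canonical_object(raw_label)))
            else:
                streams["subtask"].append(
                    SubtaskInterval(pid, canonical_subtask(raw_label), t0, t1)
                )
        except VocabularyError as err:
            raise VocabularyError(f"{path}:{line}: {err}") from None
    return by_participant


def read_event_logs(path: str | Path) -> dict[str, EventLog]:
    """Read an events CSV into one validated :class:`EventLog` per participant."""
    path = str(path)
    try:
        df = pd.read_csv(
            path, dtype={"participant": str, "label": str}, float_precision="round_trip"
        )
    except pd.errors.ParserError as err:
        raise ParseError(f"{path}: {err}") from None
    logs = {}
    for pid, streams in _parse_rows(df, path).items():
        logs[pid] = EventLog(
            participant=pid,
            fixations=streams["fixation"],
            touches=streams["touch"],
            subtasks=streams["subtask"],
        )
    return logs


def read_event_log(path: str | Path, participant: str) -> EventLog:
    """Read the events CSV and return the log of a single participant."""
    logs = read_event_logs(path)
    if participant not in logs:
        raise ValidationError(f"{path}: no rows for participant {participant!r}")
    return logs[participant]


def write_event_logs(logs: "list[EventLog] | dict[str, EventLog]", path: str | Path) -> None:
    """Write logs back to the events CSV schema (canonical labels, sorted rows)."""
    if isinstance(logs, dict):
        logs = list(logs.values())
    rows = []
    for log in logs:
        for s in log.subtasks:
            rows.append((log.participant, "subtask", s.label, s.t_start, s.t_end))
        for f in log.fixations:
            rows.append((log.participant, "fixation", f.target or "", f.t_start, f.t_end))
        for t in log.touches:
            rows.append((log.participant, "touch", t.object, t.t, t.t))
    df = pd.DataFrame(rows, columns=["participant", "stream", "label", "t_start", "t_end"])
    df = df.sort_values(["participant", "t_start", "stream"], kind="stable")
    # shortest round-trip float text so read(write(log)) is exact
    for col in ("t_start", "t_end"):
        df[col] = df[col].map(repr)
    df.to_csv(path, index=False)


def ongoing_subtask_at(log: EventLog, t: float) -> str:
    """Subtask label ongoing at time ``t`` (``approach`` in gaps).

    Intervals are half-open ``[t_start, t_end)``.  ``t`` must lie within
    ``[0, trial_duration]``.
    """
    if not 0.0 <= t <= log.trial_duration:
        raise ValueError(
            f"t={t:g} outside trial [0, {log.trial_duration:g}] ({log.participant})"
        )
    starts = [s.t_start for s in log.subtasks]
    i = bisect.bisect_right(starts, t) - 1
    if i >= 0 and log.subtasks[i].t_start <= t < log.subtasks[i].t_end:
        return log.subtasks[i].label
    return APPROACH


def non_approach_intervals(log: EventLog) -> list[SubtaskInterval]:
    """Time-ordered subtask intervals with explicit approach intervals removed."""
    return [s for s in log.subtasks if s.label != APPROACH]


def subtask_sequence(log: EventLog) -> list[str]:
    """Chronological subtask-occurrence labels (approach dropped).

    Deleting approach periods makes the flanking subtasks adjacent, so a
    subtask repeated across an approach gap yields a self-transition.
    """
    return [s.label for s in non_approach_intervals(log)]


def with_participant(log: EventLog, participant: str) -> EventLog:
    """Copy of ``log`` re-keyed to a new participant id."""
    return EventLog(
        participant=participant,
        fixations=[replace(f, participant=participant) for f in log.fixations],
        touches=[replace(t, participant=participant) for t in log.touches],
        subtasks=[replace(s, participant=participant) for s in log.subtasks],
        trial_duration=log.trial_duration,
    )
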