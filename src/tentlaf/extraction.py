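"""Look-ahead fixation (LAF) extraction from annotated event streams.

A LAF is a fixation — or a merged run of consecutive fixations — on an
object category that the participant touches later, separated from the
guiding look of that touch by at least one fixation elsewhere.  Guiding
fixations (the look that lands on the object as the hand arrives) are
excluded; a run on the instructions counts only if it is a single fixation,
since a series of fixations there is reading, not looking ahead.

Matching is by object category under the task's liberal criterion: any
later touch of the category closes the LAF, and the latency runs to the
most immediate future touch only (one LAF, one touch).  Several LAFs
revisiting the same target before its touch form a repeat group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .events import EventLog, FixationEvent, non_approach_intervals, ongoing_subtask_at
from .relevance import DEFAULT_RELEVANCE
from .vocab import APPROACH

__all__ = [
    "Segment",
    "LAFRecord",
    "merge_consecutive_fixations",
    "identify_lafs",
    "match_to_touch",
    "step_distance",
    "classify_on_off",
    "group_repeats",
    "lafs_to_frame",
    "DISCARD_REASONS",
]

#: Stable machine-readable codes for why a candidate segment was discarded.
DISCARD_REASONS = ("guiding", "no_later_touch", "instruction_multi_fixation")


@dataclass(frozen=True)
class Segment:
    """A maximal run of consecutive same-target fixations."""

    target: str
    t_start: float
    t_end: float
    duration: float  # summed fixation dwell, <= t_end - t_start
    n_fixations: int


@dataclass
class LAFRecord:
    participant: str
    target: str
    t_start: float
    t_end: float
    duration: float
    n_fixations: int
    ongoing_subtask: str
    touch_time: float
    guide_start: float | None
    latency_guide: float  # LAF end -> guiding-look start (falls back to touch)
    latency_touch: float  # LAF end -> touch
    guide_missing: bool
    step_distance: int
    step_flagged: bool
    on_task: bool | None  # None = not applicable (approach / instruction)
    latency_convention: str = "guide"
    repeat_group: str = ""
    repeat_index: int = 1

    @property
    def latency(self) -> float:
        return self.latency_touch if self.latency_convention == "touch" else self.latency_guide


def merge_consecutive_fixations(fixations: list[FixationEvent]) -> list[Segment]:
    """Merge maximal runs of consecutive fixations sharing one target.

    A run is interrupted only by a fixation on a *different* target or an
    off-object fixation; a plain time gap between two same-target fixations
    does not break the run.  Off-object fixations form no segments.
    """
    segments: list[Segment] = []
    run: list[FixationEvent] = []

    def flush() -> None:
        if run:
            segments.append(
                Segment(
                    target=run[0].target,
                    t_start=run[0].t_start,
                    t_end=run[-1].t_end,
                    duration=sum(f.duration for f in run),
                    n_fixations=len(run),
                )
            )
            run.clear()

    for f in sorted(fixations, key=lambda f: f.t_start):
        if f.target is None:
            flush()
            continue
        if run and run[-1].target != f.target:
            flush()
        run.append(f)
    flush()
    return segments


def _fixation_starts_within(fixations: list[FixationEvent], lo: float, hi: float) -> bool:
    """True if any fixation begins in the open-closed window (lo, hi]."""
    return any(lo < f.t_start <= hi for f in fixations)


def _is_guiding(segment: Segment, touches: list[float], fixations: list[FixationEvent]) -> bool:
    """Is this run the guiding look of some touch of its category?

    Either the run contains a touch of its target, or a touch follows with
    no other fixation beginning in between (the hand arrives while, or
    right after, the eyes are on the object).
    """
    for tau in touches:
        if segment.t_start <= tau <= segment.t_end:
            return True
        if tau > segment.t_end and not _fixation_starts_within(fixations, segment.t_end, tau):
            return True
    return False


def _guide_run(target: str, touch_time: float, segments: list[Segment], fixations: list[FixationEvent]):
    """The same-target run containing or immediately preceding the touch."""
    best = None
    for seg in segments:
        if seg.target != target or seg.t_start > touch_time:
            continue
        if seg.t_start <= touch_time <= seg.t_end:
            return seg
        if not _fixation_starts_within(fixations, seg.t_end, touch_time):
            best = seg
    return best


def match_to_touch(
    segment: Segment,
    touches: list[float],
    segments: list[Segment] | None = None,
    fixations: list[FixationEvent] | None = None,
) -> tuple[float, float | None, float, float]:
    """Match a segment to its most immediate future touch.

    ``touches`` are the touch times of the segment's category.  Returns
    ``(touch_time, guide_start, latency_guide, latency_touch)``; when no
    guiding run can be located the guide-based latency falls back to the
    touch itself.  Raises if no later touch exists (handled upstream).
    """
    later = [tau for tau in touches if tau > segment.t_end]
    if not later:
        raise ValueError("segment has no later touch of its category")
    touch_time = min(later)
    guide_start: float | None = None
    if segments is not None and fixations is not None:
        guide = _guide_run(segment.target, touch_time, segments, fixations)
        if guide is not None and guide.t_start > segment.t_end:
            guide_start = guide.t_start
    latency_touch = touch_time - segment.t_end
    latency_guide = (guide_start if guide_start is not None else touch_time) - segment.t_end
    return touch_time, guide_start, latency_guide, latency_touch


def step_distance(log: EventLog, laf_start: float, touch_time: float) -> tuple[int, bool]:
    """Number of non-approach subtask intervals between LAF and touch.

    The reference index is the interval containing the LAF start (the next
    interval to start when the LAF falls in approach); the touch index is
    the interval containing the touch, or the nearest following interval
    (flagged).  The distance is floored at 0.
    """
    intervals = non_approach_intervals(log)
    if not intervals:
        return 0, True

    def index_at(t: float, roll_forward: bool) -> tuple[int, bool]:
        for i, s in enumerate(intervals):
            if s.t_start <= t < s.t_end:
                return i, False
        following = [i for i, s in enumerate(intervals) if s.t_start > t]
        if following:
            return following[0], not roll_forward
        return len(intervals) - 1, True

    ref, _ = index_at(laf_start, roll_forward=True)
    touch_idx, flagged = index_at(touch_time, roll_forward=False)
    return max(touch_idx - ref, 0), flagged


def classify_on_off(
    target: str, ongoing_subtask: str, relevance: dict[str, frozenset[str]]
) -> bool | None:
    """On-task if the target is relevant to the ongoing subtask.

    Approach and instruction-reading periods are not applicable (their LAFs
    concern upcoming tasks by definition) and return ``None``.
    """
    if ongoing_subtask in (APPROACH, "read instructions"):
        return None
    return target in relevance[ongoing_subtask]


def group_repeats(lafs: list[LAFRecord]) -> list[LAFRecord]:
    """Assign repeat groups: LAFs sharing a target and matched touch.

    Repeat indices follow LAF end-time order within each group.  Mutates
    and returns the records.
    """
    groups: dict[tuple[str, str, float], list[LAFRecord]] = {}
    for laf in lafs:
        groups.setdefault((laf.participant, laf.target, laf.touch_time), []).append(laf)
    for key, members in groups.items():
        members.sort(key=lambda l: l.t_end)
        gid = f"{key[0]}:{key[1]}:{key[2]:.3f}"
        for i, laf in enumerate(members, start=1):
            laf.repeat_group = gid
            laf.repeat_index = i
    return lafs


def identify_lafs(
    log: EventLog,
    relevance: dict[str, frozenset[str]] | None = None,
    latency_convention: str = "guide",
    subtask_reference: str = "start",
) -> tuple[list[LAFRecord], Counter]:
    """Extract all LAFs from one participant's validated event log.

    Returns the records (repeat groups assigned) and a counter of discarded
    candidate segments by reason, so that segment counts reconcile:
    segments = LAFs + discards.

    ``latency_convention``: which latency populates ``LAFRecord.latency`` —
    ``"guide"`` (LAF end → guiding-look start; default) or ``"touch"``
    (LAF end → touch).  Both are always computed.
    ``subtask_reference``: whether the ongoing subtask is taken at the LAF
    start (default) or midpoint.
    """
    if latency_convention not in ("guide", "touch"):
        raise ValueError("latency_convention must be 'guide' or 'touch'")
    if subtask_reference not in ("start", "midpoint"):
        raise ValueError("subtask_reference must be 'start' or 'midpoint'")
    relevance = DEFAULT_RELEVANCE if relevance is None else relevance
    segments = merge_consecutive_fixations(log.fixations)
    touches_by_target: dict[str, list[float]] = {}
    for t in log.touches:
        touches_by_target.setdefault(t.object, []).append(t.t)
    discards: Counter = Counter()
    records: list[LAFRecord] = []
    for seg in segments:
        if seg.target == "instruction" and seg.n_fixations > 1:
            discards["instruction_multi_fixation"] += 1
            continue
        target_touches = touches_by_target.get(seg.target, [])
        if _is_guiding(seg, target_touches, log.fixations):
            discards["guiding"] += 1
            continue
        if not any(tau > seg.t_end for tau in target_touches):
            discards["no_later_touch"] += 1
            continue
        touch_time, guide_start, lat_guide, lat_touch = match_to_touch(
            seg, target_touches, segments, log.fixations
        )
        t_ref = seg.t_start if subtask_reference == "start" else (seg.t_start + seg.t_end) / 2
        ongoing = ongoing_subtask_at(log, min(t_ref, log.trial_duration))
        dist, flagged = step_distance(log, seg.t_start, touch_time)
        records.append(
            LAFRecord(
                participant=log.participant,
                target=seg.target,
                t_start=seg.t_start,
                t_end=seg.t_end,
                duration=seg.duration,
                n_fixations=seg.n_fixations,
                ongoing_subtask=ongoing,
                touch_time=touch_time,
                guide_start=guide_start,
                latency_guide=lat_guide,
                latency_touch=lat_touch,
                guide_missing=guide_start is None,
                step_distance=dist,
                step_flagged=flagged,
                on_task=classify_on_off(seg.target, ongoing, relevance),
                latency_convention=latency_convention,
            )
        )
    return group_repeats(records), discards


LAF_COLUMNS = [
    "participant",
    "target",
    "t_start",
    "t_end",
    "duration",
    "n_fixations",
    "ongoing_subtask",
    "touch_time",
    "guide_start",
    "latency_guide",
    "latency_touch",
    "step_distance",
    "on_task",
    "repeat_group",
    "repeat_index",
]


def lafs_to_frame(lafs: list[LAFRecord]) -> pd.DataFrame:
    """Tidy one-row-per-LAF table (both latency conventions included)."""
    rows = []
    for l in lafs:
        rows.append(
            {
                "participant": l.participant,
                "target": l.target,
                "t_start": l.t_start,
                "t_end": l.t_end,
                "duration": l.duration,
                "n_fixations": l.n_fixations,
                "ongoing_subtask": l.ongoing_subtask,
                "touch_time": l.touch_time,
                "guide_start": l.guide_start,
                "latency_guide": l.latency_guide,
                "latency_touch": l.latency_touch,
                "step_distance": l.step_distance,
                "on_task": "NA" if l.on_task is None else bool(l.on_task),
                "repeat_group": l.repeat_group,
                "repeat_index": l.repeat_index,
            }
        )
    return pd.DataFrame(rows, columns=LAF_COLUMNS)


def frame_to_lafs(df: pd.DataFrame, latency_convention: str = "guide") -> list[LAFRecord]:
    """Rebuild LAF records from the tidy table written by :func:`lafs_to_frame`."""
    missing = [c for c in LAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"LAF table missing column(s): {missing}")
    out = []
    for row in df.itertuples(index=False):
        on_task = None if str(row.on_task) == "NA" else str(row.on_task) == "True"
        guide_start = None if pd.isna(row.guide_start) else float(row.guide_start)
        out.append(
            LAFRecord(
                participant=str(row.participant),
                target=row.target,
                t_start=float(row.t_start),
                t_end=float(row.t_end),
                duration=float(row.duration),
                n_fixations=int(row.n_fixations),
                ongoing_subtask=row.ongoing_subtask,
                touch_time=float(row.touch_time),
                guide_start=guide_start,
                latency_guide=float(row.latency_guide),
                latency_touch=float(row.latency_touch),
                guide_missing=guide_start is None,
                step_distance=int(row.step_distance),
                step_flagged=False,
                on_task=on_task,
                latency_convention=latency_convention,
                repeat_group=str(row.repeat_group),
                repeat_index=int(row.repeat_index),
            )
        )
    return out
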