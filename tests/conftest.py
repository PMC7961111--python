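"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive the extraction and scoring rules in the
most literal way possible (scan runs, test every run/touch pair, sum terms
one by one) so they stay independent of the library's implementation.
"""

from __future__ import annotations

import math
import random

import pytest

from tentlaf.events import EventLog, FixationEvent, SubtaskInterval, TouchEvent
from tentlaf.vocab import OBJECT_LABELS, SUBTASK_LABELS


def brute_force_runs(fixations):
    """Literal run-length scan: lists of consecutive same-target fixations."""
    runs, current = [], []
    for f in sorted(fixations, key=lambda f: f.t_start):
        if f.target is None:
            if current:
                runs.append(current)
            current = []
        elif current and current[-1].target == f.target:
            current.append(f)
        else:
            if current:
                runs.append(current)
            current = [f]
    if current:
        runs.append(current)
    return runs


def brute_force_lafs(log: EventLog):
    """Enumerate every (run, touch) pair against the defining rules.

    A run qualifies as an LAF iff: it is not a multi-fixation run on the
    instructions; it is not the guiding look of any touch of its category
    (no touch inside the run, and no later touch without an intervening
    fixation of any kind); and a later touch of its category exists.  The
    match is the most immediate later touch.  Returns
    (target, t_start, t_end, touch_time) tuples.
    """
    out = []
    for run in brute_force_runs(log.fixations):
        target = run[0].target
        start, end = run[0].t_start, run[-1].t_end
        if target == "instruction" and len(run) > 1:
            continue
        taus = sorted(t.t for t in log.touches if t.object == target)
        guiding = False
        for tau in taus:
            if start <= tau <= end:
                guiding = True
            elif tau > end and not any(end < f.t_start <= tau for f in log.fixations):
                guiding = True
        if guiding:
            continue
        later = [tau for tau in taus if tau > end]
        if not later:
            continue
        out.append((target, start, end, min(later)))
    return out


def brute_force_path_score(labels, matrix) -> float:
    """Term-by-term log-probability summation against a transition matrix."""
    total = 0.0
    for a, b in zip(labels, labels[1:]):
        p = matrix.P[matrix.states.index(a), matrix.states.index(b)]
        if p <= 0:
            return -math.inf
        total += math.log(p)
    return total


def random_log(rng: random.Random, max_events: int = 50, participant: str = "px") -> EventLog:
    """A small random but invariant-satisfying event log.

    Sequential fixations with random targets (including off-object),
    scattered touches, and a few non-overlapping subtask intervals.
    """
    targets = list(OBJECT_LABELS) + [None, None]
    n_fix = rng.randint(1, max(1, max_events - 10))
    fixations, t = [], rng.uniform(0.0, 2.0)
    for _ in range(n_fix):
        dur = rng.uniform(0.1, 0.8)
        fixations.append(FixationEvent(participant, t, t + dur, rng.choice(targets)))
        t += dur + rng.uniform(0.0, 0.6)
    horizon = t + 5.0
    n_touch = rng.randint(0, min(10, max_events - n_fix))
    touches = [
        TouchEvent(participant, rng.uniform(0.0, horizon), rng.choice(OBJECT_LABELS))
        for _ in range(n_touch)
    ]
    intervals, t0 = [], rng.uniform(0.0, 1.0)
    for _ in range(rng.randint(1, 5)):
        dur = rng.uniform(1.0, horizon / 2)
        intervals.append(
            SubtaskInterval(participant, rng.choice(SUBTASK_LABELS), t0, t0 + dur)
        )
        t0 += dur + rng.uniform(0.0, 2.0)
    return EventLog(
        participant=participant,
        fixations=fixations,
        touches=touches,
        subtasks=intervals,
        trial_duration=max(horizon, t0) + 1.0,
    )


@pytest.fixture
def tiny_log() -> EventLog:
    """Hand-built log with one clear LAF, one guiding look, and one touch.

    Gaze: guyline look-ahead at 10–10.8 (two merged fixations), a tent
    fixation elsewhere, then the guiding look at 38.5 that accompanies the
    guyline touch at 40.
    """
    p = "p1"
    return EventLog(
        participant=p,
        fixations=[
            FixationEvent(p, 10.0, 10.3, "guyline"),
            FixationEvent(p, 10.4, 10.8, "guyline"),
            FixationEvent(p, 12.0, 12.5, "tent"),
            FixationEvent(p, 38.5, 40.0, "guyline"),
        ],
        touches=[TouchEvent(p, 40.0, "guyline")],
        subtasks=[
            SubtaskInterval(p, "stake corner", 5.0, 20.0),
            SubtaskInterval(p, "place guyline", 30.0, 50.0),
        ],
        trial_duration=60.0,
    )
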