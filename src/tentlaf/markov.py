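"""Subtask-sequence compression, transition matrices, and path scoring.

A participant's chronological subtask occurrences are treated as states of a
first-order Markov chain over the 12 subtask labels (approach is never a
state: approach periods are deleted so flanking subtasks become adjacent).
Self-transitions are counted — subtasks done in immediate repetition
(staking four corners, placing four guylines) put mass on the diagonal.

Sequences are scored against an idealized reference matrix built from the
packaged step outline, with a small probability floor (default 1e-6)
replacing structurally-zero transitions so every path has finite
log-probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventLog, non_approach_intervals, subtask_sequence
from .reference import IDEALIZED_SEQUENCE, step_act, step_label
from .stats import RegressionResult, ols_fit
from .vocab import APPROACH, SUBTASK_LABELS

__all__ = [
    "TransitionMatrix",
    "PathScore",
    "compress_steps",
    "count_transitions",
    "average_matrices",
    "idealized_matrix",
    "path_log_probability",
    "subtask_duration_stats",
    "bottleneck_regressions",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix with its count provenance.

    Rows whose count total is zero (state never left) are all-zero in ``P``.
    """

    states: tuple[str, ...]
    counts: np.ndarray  # (n, n) nonnegative
    P: np.ndarray  # (n, n) probabilities

    @classmethod
    def from_counts(cls, counts: np.ndarray, states: tuple[str, ...] = SUBTASK_LABELS) -> "TransitionMatrix":
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(states), len(states)):
            raise ValueError("counts shape does not match states")
        if (counts < 0).any():
            raise ValueError("negative transition counts")
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 0.0)
        return cls(states=tuple(states), counts=counts, P=P)

    def index(self, label: str) -> int:
        return self.states.index(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(self.states), columns=list(self.states))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        states = tuple(df.index)
        P = df.to_numpy(dtype=float)
        obj = cls(states=states, counts=np.zeros_like(P), P=P)
        return obj


@dataclass
class PathScore:
    """Natural-log probability of a subtask path under a reference matrix."""

    log_prob: float  # <= 0; -inf if a zero-probability transition occurred
    n_transitions: int
    hit_zero: bool = False


def compress_steps(steps: list[str]) -> list[str]:
    """Compress a mid-level step sequence to subtask-label occurrences.

    Consecutive steps belonging to the same grouped act merge into one
    occurrence of that act's label; repeated acts (staking each corner) are
    retained as separate occurrences even when their labels coincide.
    """
    out: list[str] = []
    prev_act: int | None = None
    for step in steps:
        label, act = step_label(step), step_act(step)
        if act != prev_act:
            out.append(label)
        prev_act = act
    return out


def count_transitions(
    labels: list[str], states: tuple[str, ...] = SUBTASK_LABELS
) -> TransitionMatrix:
    """Count adjacent-pair transitions of a subtask-occurrence sequence.

    Self-transitions are counted.  Sequences shorter than 2 yield an
    all-zero matrix.  Approach must be removed beforehand.
    """
    if APPROACH in labels:
        raise ValueError("approach occurrences must be dropped before counting")
    idx = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    for a, b in zip(labels, labels[1:]):
        counts[idx[a], idx[b]] += 1
    return TransitionMatrix.from_counts(counts, states)


def average_matrices(ms: list[TransitionMatrix]) -> TransitionMatrix:
    """Elementwise mean of per-participant transition probabilities.

    Each row is averaged over the participants who actually visited (and
    left) that state, so averaged rows stay interpretable as conditional
    probabilities.  Count provenance is summed.
    """
    if not ms:
        raise ValueError("average_matrices requires at least one matrix")
    states = ms[0].states
    for m in ms[1:]:
        if m.states != states:
            raise ValueError("all matrices must share state ordering")
    n = len(states)
    acc = np.zeros((n, n))
    contributors = np.zeros(n)
    counts = np.zeros((n, n))
    for m in ms:
        visited = m.counts.sum(axis=1) > 0
        acc[visited] += m.P[visited]
        contributors += visited
        counts += m.counts
    P = np.zeros((n, n))
    rows = contributors > 0
    P[rows] = acc[rows] / contributors[rows, None]
    return TransitionMatrix(states=states, counts=counts, P=P)


def idealized_matrix(
    reference: "list[str] | tuple[str, ...]" = IDEALIZED_SEQUENCE,
    floor: float = 1e-6,
    renormalize: bool = True,
    states: tuple[str, ...] = SUBTASK_LABELS,
) -> TransitionMatrix:
    """Reference matrix of the idealized sequence with a probability floor.

    The reference sequence is counted and row-normalized, then every zero
    entry is replaced by ``floor``.  With ``renormalize`` (default) each row
    is rescaled to sum to exactly 1; the alternative leaves the floored
    values inserted as-is.
    """
    if not len(reference):
        raise ValueError("reference sequence must be nonempty")
    if not floor > 0:
        raise ValueError("floor must be > 0")
    m = count_transitions(list(reference), states)
    P = m.P.copy()
    positive = P[P > 0]
    if positive.size and floor >= positive.min():
        raise ValueError("floor must be smaller than the smallest positive probability")
    P[P == 0] = floor
    if renormalize:
        P = P / P.sum(axis=1, keepdims=True)
    return TransitionMatrix(states=m.states, counts=m.counts, P=P)


def path_log_probability(labels: list[str], m: TransitionMatrix) -> PathScore:
    """Sum of natural-log transition probabilities along a path.

    No initial-state term.  A zero-probability transition yields ``-inf``
    with ``hit_zero`` set (cannot occur against a floored idealized matrix).
    """
    idx = {s: i for i, s in enumerate(m.states)}
    total = 0.0
    hit_zero = False
    for a, b in zip(labels, labels[1:]):
        p = m.P[idx[a], idx[b]]
        if p <= 0.0:
            hit_zero = True
            total = -np.inf
            break
        total += float(np.log(p))
    return PathScore(log_prob=total, n_transitions=max(len(labels) - 1, 0), hit_zero=hit_zero)


def subtask_duration_stats(logs: list[EventLog]) -> pd.DataFrame:
    """Across-participant summary of total time spent per subtask label.

    Per participant, the total is the sum of that label's interval lengths
    (0 for labels the participant never performed).  Returns mean, sample
    SD, min and max across participants, indexed by label.
    """
    totals = pd.DataFrame(0.0, index=[l.participant for l in logs], columns=list(SUBTASK_LABELS))
    for log in logs:
        for s in non_approach_intervals(log):
            totals.loc[log.participant, s.label] += s.duration
    out = pd.DataFrame(
        {
            "mean": totals.mean(axis=0),
            "sd": totals.std(axis=0, ddof=1),
            "min": totals.min(axis=0),
            "max": totals.max(axis=0),
        }
    )
    out.index.name = "subtask"
    return out


def bottleneck_regressions(logs: list[EventLog], alpha: float = 0.004) -> pd.DataFrame:
    """Per-subtask bottleneck test: does time on a subtask predict the rest?

    For each label ``s``, simple OLS of (trial_duration − duration_s) on
    duration_s across participants, Bonferroni-style fixed ``alpha``
    (default 0.004).  Labels with zero predictor variance are flagged
    undefined rather than raising.
    """
    if len(logs) < 3:
        raise ValueError("bottleneck_regressions requires at least 3 participants")
    rows = []
    durations = {log.participant: dict.fromkeys(SUBTASK_LABELS, 0.0) for log in logs}
    trial = {}
    for log in logs:
        trial[log.participant] = log.trial_duration
        for s in non_approach_intervals(log):
            durations[log.participant][s.label] += s.duration
    pids = [log.participant for log in logs]
    for label in SUBTASK_LABELS:
        x = np.array([durations[p][label] for p in pids])
        y = np.array([trial[p] - durations[p][label] for p in pids])
        res = ols_fit(x, y)
        rows.append(
            {
                "subtask": label,
                "beta": res.beta,
                "intercept": res.intercept,
                "r2": res.r2,
                "F": res.F,
                "df1": res.df[0],
                "df2": res.df[1],
                "p": res.p,
                "defined": res.defined,
                "significant": bool(res.defined and res.p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("subtask")


def participant_matrices(logs: list[EventLog]) -> list[TransitionMatrix]:
    """Per-participant transition matrices from validated event logs."""
    return [count_transitions(subtask_sequence(log)) for log in logs]
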