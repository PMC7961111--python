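"""Descriptive and inferential statistics over LAF records and event logs.

Simple OLS and the two-sample t-test are thin, fully-specified wrappers
around scipy so that every number the pipeline reports (β, R², F, df, p;
t, df, p) has an explicit closed-form meaning.  The pooled-variance
Student's t is the default (df = n1 + n2 − 2); Welch's variant is a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "RegressionResult",
    "TTestResult",
    "LatencyDistribution",
    "summarize",
    "ols_fit",
    "two_sample_t",
    "latency_distribution",
    "laf_rate",
    "target_task_crosstab",
    "on_task_fraction",
    "repeat_summary",
    "experience_score",
    "calibration_error",
]


@dataclass
class SummaryStats:
    M: float
    SD: float
    median: float
    range: tuple[float, float]
    n: int


def summarize(values) -> SummaryStats:
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    return SummaryStats(
        M=float(x.mean()),
        SD=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        range=(float(x.min()), float(x.max())),
        n=int(x.size),
    )


@dataclass
class RegressionResult:
    """Simple-OLS summary: response = intercept + beta * predictor."""

    beta: float
    intercept: float
    r2: float
    F: float
    df: tuple[int, int]  # (1, n - 2)
    p: float
    defined: bool = True


def ols_fit(x, y) -> RegressionResult:
    """Simple linear regression with the standard F(1, n−2) test.

    A constant predictor yields an undefined result (``defined=False``)
    rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("ols_fit requires n >= 3")
    if y.size != n:
        raise ValueError("x and y must have equal length")
    df = (1, n - 2)
    if np.ptp(x) == 0.0:
        return RegressionResult(math.nan, math.nan, math.nan, math.nan, df, math.nan, defined=False)
    if np.ptp(y) == 0.0:
        # constant response: zero slope explains all (zero) variance
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, df, 1.0)
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        F = math.inf
        p = 0.0
    else:
        F = r2 / (1.0 - r2) * (n - 2)
        p = float(sps.f.sf(F, 1, n - 2))
    return RegressionResult(
        beta=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        F=float(F),
        df=df,
        p=p,
    )


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    group1: SummaryStats
    group2: SummaryStats
    pooled: bool = True
    defined: bool = True


def two_sample_t(x, y, pooled: bool = True) -> TTestResult:
    """Two-sided two-sample t-test (pooled Student's t by default).

    Pooled df is n1 + n2 − 2; the Welch variant uses the
    Welch–Satterthwaite df.  Zero variance in both groups yields an
    undefined result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    g1, g2 = summarize(x), summarize(y)
    n1, n2 = x.size, y.size
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if pooled:
        df: float = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        denom = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        a, b = v1 / n1, v2 / n2
        denom = math.sqrt(a + b)
        if v1 == 0.0 and v2 == 0.0:
            df = float(n1 + n2 - 2)
        else:
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    if denom == 0.0:
        if g1.M == g2.M:
            return TTestResult(0.0, df, 1.0, g1, g2, pooled)
        return TTestResult(math.nan, df, math.nan, g1, g2, pooled, defined=False)
    t = (g1.M - g2.M) / denom
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, g1, g2, pooled)


@dataclass
class LatencyDistribution:
    """Histogram plus empirical cumulative shares of LAF latencies.

    ``bin_edges`` has one more entry than ``frequencies``; ``cumulative``
    holds P(latency < edge) at each right edge and ends at 1.
    """

    bin_edges: np.ndarray
    frequencies: np.ndarray
    cumulative: np.ndarray
    mode: str = "time"  # "time" (seconds) or "steps"

    @classmethod
    def from_counts(cls, bin_edges, frequencies, mode: str = "time") -> "LatencyDistribution":
        edges = np.asarray(bin_edges, dtype=float)
        freq = np.asarray(frequencies, dtype=float)
        if edges.size != freq.size + 1:
            raise ValueError("need len(bin_edges) == len(frequencies) + 1")
        total = freq.sum()
        if total <= 0:
            raise ValueError("empty distribution")
        return cls(edges, freq, np.cumsum(freq) / total, mode)

    @property
    def total(self) -> float:
        return float(self.frequencies.sum())

    def share_below(self, threshold: float) -> float:
        """Cumulative share of latencies below a bin edge ``threshold``."""
        edges = self.bin_edges[1:]
        i = int(np.searchsorted(edges, threshold))
        if i >= edges.size:
            return 1.0
        if not math.isclose(edges[i], threshold):
            raise ValueError(f"threshold {threshold:g} is not a bin edge")
        return float(self.cumulative[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "frequency": self.frequencies,
                "cumulative": self.cumulative,
            }
        )


def latency_distribution(lafs, mode: str = "time", bin_width: float | None = None) -> LatencyDistribution:
    """Histogram/CDF of LAF latencies in seconds or in subtask steps.

    Default bin width is 10 s in time mode and 1 step in steps mode.  Step
    bins are centered on integers (step d falls in [d−0.5, d+0.5)).
    """
    lafs = list(lafs)
    if not lafs:
        raise ValueError("latency_distribution needs at least one LAF")
    if mode == "time":
        bw = 10.0 if bin_width is None else float(bin_width)
        values = np.array([l.latency for l in lafs], dtype=float)
        top = max(values.max(), bw)
        edges = np.arange(0.0, math.ceil(top / bw) * bw + bw / 2, bw)
    elif mode == "steps":
        bw = 1.0 if bin_width is None else float(bin_width)
        values = np.array([l.step_distance for l in lafs], dtype=float)
        edges = np.arange(-bw / 2, values.max() + bw, bw)
    else:
        raise ValueError("mode must be 'time' or 'steps'")
    freq, edges = np.histogram(values, bins=edges)
    return LatencyDistribution.from_counts(edges, freq, mode)


def laf_rate(lafs, log) -> float:
    """LAFs per minute for one participant's log."""
    if log.trial_duration <= 0:
        raise ValueError("trial duration must be positive")
    return len(list(lafs)) / (log.trial_duration / 60.0)


def target_task_crosstab(lafs) -> pd.DataFrame:
    """Frequency table of ongoing subtask (rows) × LAF target (columns).

    Includes 'All' marginals; cells sum to the total LAF count.
    """
    lafs = list(lafs)
    from .vocab import APPROACH, OBJECT_LABELS, SUBTASK_LABELS

    rows = list(SUBTASK_LABELS) + [APPROACH]
    cols = list(OBJECT_LABELS)
    table = pd.DataFrame(0, index=rows, columns=cols)
    for laf in lafs:
        table.loc[laf.ongoing_subtask, laf.target] += 1
    table["All"] = table.sum(axis=1)
    table.loc["All"] = table.sum(axis=0)
    table.index.name = "subtask"
    return table


def on_task_fraction(lafs, per_participant: bool = False):
    """Fraction of applicable LAFs whose target is relevant to the ongoing task.

    LAFs made during approach or instruction reading are not applicable and
    are excluded.  Returns NaN when no applicable LAFs exist.  With
    ``per_participant`` the fractions are computed per participant and the
    unweighted mean across participants is returned alongside the
    per-participant series.
    """
    applicable = [l for l in lafs if l.on_task is not None]
    if not per_participant:
        if not applicable:
            return math.nan
        return sum(1 for l in applicable if l.on_task) / len(applicable)
    by_pid: dict[str, list] = {}
    for l in applicable:
        by_pid.setdefault(l.participant, []).append(l)
    series = pd.Series(
        {pid: sum(1 for l in ls if l.on_task) / len(ls) for pid, ls in by_pid.items()}
    )
    return (float(series.mean()) if len(series) else math.nan), series


def repeat_summary(lafs) -> dict:
    """Repeat-group accounting: isolated vs multi-LAF groups and revisit gaps."""
    groups: dict[str, list] = {}
    for l in lafs:
        groups.setdefault(l.repeat_group, []).append(l)
    sizes = np.array([len(g) for g in groups.values()], dtype=int)
    gaps: list[float] = []
    for g in groups.values():
        ends = sorted(l.t_end for l in g)
        gaps.extend(b - a for a, b in zip(ends, ends[1:]))
    n_multi_groups = int((sizes >= 2).sum())
    return {
        "n_lafs": int(sizes.sum()),
        "n_groups": int(sizes.size),
        "n_isolated": int((sizes == 1).sum()),
        "n_multi_groups": n_multi_groups,
        "n_lafs_in_multi": int(sizes[sizes >= 2].sum()),
        "revisited_fraction": (n_multi_groups / sizes.size) if sizes.size else math.nan,
        "inter_repeat_gaps": gaps,
    }


_EXPERIENCE_CODES = {"low": 0.0, "medium": 0.5, "high": 1.0}
_YESNO_CODES = {"yes": 1.0, "no": 0.0, "1": 1.0, "0": 0.0, "true": 1.0, "false": 0.0}

QUESTIONNAIRE_ITEMS = (
    "camps_per_year",
    "experience_level",
    "owns_tent",
    "setups_per_year",
    "lifetime_setups",
)


def _code_item(item: str, value) -> float:
    if pd.isna(value):
        raise ValueError(f"missing questionnaire response for {item}")
    if item == "experience_level":
        key = str(value).strip().lower()
        if key in _EXPERIENCE_CODES:
            return _EXPERIENCE_CODES[key]
        return float(value)
    if item == "owns_tent":
        key = str(value).strip().lower()
        if key in _YESNO_CODES:
            return _YESNO_CODES[key]
        return float(value)
    return float(value)


def experience_score(responses: pd.DataFrame, scale_max: dict | None = None) -> pd.Series:
    """Composite experience score in [0, 1] per participant.

    Categorical items are coded first (low/medium/high → 0/0.5/1; tent
    ownership yes/no → 1/0).  Each item is then divided by the cohort
    maximum for that item (items whose maximum is 0 contribute 0) and the
    five normalized items are averaged with equal weight.  ``scale_max``
    overrides the observed cohort maximum per item.
    """
    df = responses.set_index("participant") if "participant" in responses.columns else responses
    missing = [c for c in QUESTIONNAIRE_ITEMS if c not in df.columns]
    if missing:
        raise ValueError(f"questionnaire missing item(s): {missing}")
    coded = pd.DataFrame(
        {item: df[item].map(lambda v, item=item: _code_item(item, v)) for item in QUESTIONNAIRE_ITEMS},
        index=df.index,
    )
    maxima = coded.max(axis=0)
    if scale_max:
        for item, m in scale_max.items():
            maxima[item] = float(m)
    normalized = coded.copy()
    for item in QUESTIONNAIRE_ITEMS:
        normalized[item] = 0.0 if maxima[item] == 0 else coded[item] / maxima[item]
    return normalized.mean(axis=1).rename("experience_score")


def calibration_error(
    points: pd.DataFrame, threshold_deg: float = 5.0
) -> tuple[pd.DataFrame, SummaryStats]:
    """Per-participant median calibration error and the inclusion rule.

    ``points`` columns: participant, phase (pre|post), gaze_x_deg,
    gaze_y_deg, target_x_deg, target_y_deg.  The per-point error is the
    Euclidean gaze–target distance in degrees; the per-participant summary
    is the median per phase.  A participant is excluded when the mean of
    the pre- and post-phase medians exceeds ``threshold_deg`` (if a phase
    is missing the available phase stands in, flagged).

    Returns the per-participant table and cohort summary stats of the
    pre/post-average medians.
    """
    df = points.copy()
    df["error_deg"] = np.hypot(
        df["gaze_x_deg"] - df["target_x_deg"], df["gaze_y_deg"] - df["target_y_deg"]
    )
    medians = df.groupby(["participant", "phase"])["error_deg"].median().unstack("phase")
    out = pd.DataFrame(index=medians.index)
    out["pre_median_deg"] = medians.get("pre")
    out["post_median_deg"] = medians.get("post")
    out["phase_missing"] = out[["pre_median_deg", "post_median_deg"]].isna().any(axis=1)
    out["mean_error_deg"] = out[["pre_median_deg", "post_median_deg"]].mean(axis=1)
    out["included"] = out["mean_error_deg"] <= threshold_deg
    cohort = summarize(out["mean_error_deg"].dropna())
    return out, cohort
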