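"""Statistics: distributions, rates, crosstabs, t-test/OLS closed forms."""

from __future__ import annotations

import math
import random
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tentlaf.events import EventLog
from tentlaf.stats import (
    LatencyDistribution,
    calibration_error,
    experience_score,
    laf_rate,
    latency_distribution,
    ols_fit,
    on_task_fraction,
    repeat_summary,
    summarize,
    target_task_crosstab,
    two_sample_t,
)


def _laf(**kw):
    base = dict(
        participant="p1",
        target="guyline",
        ongoing_subtask="stake corner",
        latency=5.0,
        step_distance=1,
        on_task=True,
        t_end=10.0,
        repeat_group="g1",
    )
    base.update(kw)
    return SimpleNamespace(**base)


class TestLatencyDistribution:
    def test_direct_binning(self):
        lafs = [_laf(latency=v) for v in (5.0, 15.0, 25.0)]
        d = latency_distribution(lafs, mode="time", bin_width=10.0)
        assert list(d.frequencies) == [1, 1, 1]
        assert np.allclose(d.cumulative, [1 / 3, 2 / 3, 1.0])

    def test_identical_latencies_single_bin(self):
        d = latency_distribution([_laf(latency=4.0)] * 5, mode="time")
        assert d.frequencies.sum() == 5
        assert (d.frequencies > 0).sum() == 1
        assert d.cumulative[-1] == pytest.approx(1.0)

    def test_step_mode_totals_match_time_mode(self):
        rng = random.Random(1)
        lafs = [
            _laf(latency=rng.uniform(0.1, 300), step_distance=rng.randint(0, 20))
            for _ in range(200)
        ]
        t = latency_distribution(lafs, mode="time")
        s = latency_distribution(lafs, mode="steps")
        assert t.total == s.total == 200
        for d in (t, s):
            assert (np.diff(d.cumulative) >= -1e-12).all()
            assert d.cumulative[-1] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            latency_distribution([], mode="time")

    def test_share_below_requires_bin_edge(self):
        d = LatencyDistribution.from_counts([0, 10, 100], [35, 40])
        assert d.share_below(10) == pytest.approx(35 / 75)
        with pytest.raises(ValueError):
            d.share_below(37.0)


class TestLafRate:
    def test_rate_arithmetic(self):
        log = EventLog("p1", trial_duration=300.0)
        assert laf_rate([_laf()] * 10, log) == pytest.approx(2.0)
        assert laf_rate([], log) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            laf_rate([], EventLog("p1", trial_duration=0.0))


class TestCrosstab:
    def test_single_cell(self):
        lafs = [_laf(ongoing_subtask="approach", target="guyline")] * 3
        table = target_task_crosstab(lafs)
        assert table.loc["approach", "guyline"] == 3
        assert table.loc["approach", "All"] == 3
        assert table.loc["All", "guyline"] == 3

    def test_empty_all_zero(self):
        table = target_task_crosstab([])
        assert table.loc["All", "All"] == 0

    def test_marginals_match_brute_tally(self):
        rng = random.Random(2)
        from tentlaf.vocab import OBJECT_LABELS, SUBTASK_LABELS

        lafs = [
            _laf(
                ongoing_subtask=rng.choice(SUBTASK_LABELS),
                target=rng.choice(OBJECT_LABELS),
            )
            for _ in range(150)
        ]
        table = target_task_crosstab(lafs)
        assert table.loc["All", "All"] == 150
        for sub in {l.ongoing_subtask for l in lafs}:
            assert table.loc[sub, "All"] == sum(l.ongoing_subtask == sub for l in lafs)
        for obj in {l.target for l in lafs}:
            assert table.loc["All", obj] == sum(l.target == obj for l in lafs)


class TestOnTaskFraction:
    def test_not_applicable_excluded(self):
        lafs = [
            _laf(on_task=True),
            _laf(on_task=True),
            _laf(on_task=False),
            _laf(on_task=False),
            _laf(on_task=None),
        ]
        assert on_task_fraction(lafs) == pytest.approx(0.5)

    def test_all_not_applicable_undefined(self):
        assert math.isnan(on_task_fraction([_laf(on_task=None)]))

    def test_per_participant_mean(self):
        lafs = [
            _laf(participant="a", on_task=True),
            _laf(participant="a", on_task=False),
            _laf(participant="b", on_task=True),
        ]
        mean, series = on_task_fraction(lafs, per_participant=True)
        assert series["a"] == pytest.approx(0.5)
        assert series["b"] == pytest.approx(1.0)
        assert mean == pytest.approx(0.75)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_hand_computed_pooled_formulas(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = two_sample_t(x, y)
        # hand: means 2 and 5, pooled variance ((2)+(2))/4 = 1
        t_hand = (2.0 - 5.0) / math.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert res.t == pytest.approx(t_hand, abs=1e-10)
        assert res.df == 4
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_hand), 4), abs=1e-10)

    def test_pooled_df_formula(self):
        rng = np.random.default_rng(0)
        res = two_sample_t(rng.normal(size=200), rng.normal(size=247))
        assert res.df == 445

    def test_welch_variant_differs(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 20), rng.normal(0, 5, 10)
        pooled = two_sample_t(x, y, pooled=True)
        welch = two_sample_t(x, y, pooled=False)
        assert welch.df != pooled.df
        assert welch.df == pytest.approx(
            (x.var(ddof=1) / 20 + y.var(ddof=1) / 10) ** 2
            / ((x.var(ddof=1) / 20) ** 2 / 19 + (y.var(ddof=1) / 10) ** 2 / 9)
        )

    def test_zero_variance_undefined(self):
        res = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert not res.defined


class TestOlsFit:
    def test_exact_line(self):
        x = np.arange(1.0, 7.0)
        res = ols_fit(x, 2 * x)
        assert res.beta == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        x = np.arange(1.0, 7.0)
        res = ols_fit(x, np.full(6, 3.0))
        assert res.beta == pytest.approx(0.0)
        assert res.r2 == pytest.approx(0.0)

    def test_matches_hand_closed_forms(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, size=12)
        y = 1.5 * x + rng.normal(0, 2, size=12)
        res = ols_fit(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        beta = sxy / sxx
        r2 = sxy**2 / (sxx * syy)
        F = r2 / (1 - r2) * (len(x) - 2)
        assert res.beta == pytest.approx(beta, abs=1e-10)
        assert res.intercept == pytest.approx(y.mean() - beta * x.mean(), abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        assert res.F == pytest.approx(F, abs=1e-8)
        assert res.p == pytest.approx(float(sps.f.sf(F, 1, 10)), abs=1e-10)
        assert res.df == (1, 10)

    def test_degenerate_predictor_flagged(self):
        res = ols_fit(np.full(5, 2.0), np.arange(5.0))
        assert not res.defined


class TestRepeatSummary:
    def test_partition_and_gaps(self):
        lafs = [
            _laf(repeat_group="g1", t_end=10.0),
            _laf(repeat_group="g1", t_end=50.0),
            _laf(repeat_group="g2", t_end=30.0),
        ]
        rep = repeat_summary(lafs)
        assert rep["n_lafs"] == 3
        assert rep["n_isolated"] == 1
        assert rep["n_lafs_in_multi"] == 2
        assert rep["n_lafs"] - rep["n_isolated"] == rep["n_lafs_in_multi"]
        assert rep["inter_repeat_gaps"] == [40.0]
        assert rep["revisited_fraction"] == pytest.approx(0.5)


def _questionnaire(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "camps_per_year",
            "experience_level",
            "owns_tent",
            "setups_per_year",
            "lifetime_setups",
        ],
    )


class TestExperienceScore:
    def test_extremes(self):
        df = _questionnaire(
            [
                ["lo", 0, "low", "no", 0, 0],
                ["hi", 4, "high", "yes", 6, 30],
            ]
        )
        scores = experience_score(df)
        assert scores["lo"] == pytest.approx(0.0)
        assert scores["hi"] == pytest.approx(1.0)

    def test_medium_codes_half_before_normalization(self):
        df = _questionnaire(
            [
                ["a", 0, "medium", "no", 0, 0],
                ["b", 0, "high", "no", 0, 0],
            ]
        )
        scores = experience_score(df)
        # only the experience item varies: medium/high = 0.5 after max-normalization
        assert scores["a"] == pytest.approx(0.1)  # 0.5 / 1.0 averaged over 5 items
        assert scores["b"] == pytest.approx(0.2)

    def test_missing_response_rejected(self):
        df = _questionnaire([["a", 1, None, "no", 0, 0]])
        with pytest.raises(ValueError):
            experience_score(df)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 10),
                st.sampled_from(["low", "medium", "high"]),
                st.sampled_from(["yes", "no"]),
                st.integers(0, 10),
                st.integers(0, 50),
            ),
            min_size=2,
            max_size=8,
        ),
        st.integers(0, 10),
    )
    def test_bounded_and_monotone(self, rows, bump):
        df = _questionnaire([[f"p{i}", *r] for i, r in enumerate(rows)])
        scores = experience_score(df)
        assert ((scores >= 0) & (scores <= 1 + 1e-12)).all()
        # raising one participant's numeric response never lowers their score
        df2 = df.copy()
        df2.loc[0, "camps_per_year"] += bump
        assert experience_score(df2)["p0"] >= scores["p0"] - 1e-12


class TestCalibration:
    def _points(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "participant",
                "phase",
                "gaze_x_deg",
                "gaze_y_deg",
                "target_x_deg",
                "target_y_deg",
            ],
        )

    def test_perfect_gaze_zero_error(self):
        df = self._points([["a", "pre", 1, 2, 1, 2], ["a", "post", 3, 4, 3, 4]])
        table, cohort = calibration_error(df)
        assert table.loc["a", "mean_error_deg"] == pytest.approx(0.0)
        assert bool(table.loc["a", "included"])

    def test_three_four_five(self):
        df = self._points([["a", "pre", 0, 0, 3, 4]])
        table, _ = calibration_error(df)
        assert table.loc["a", "pre_median_deg"] == pytest.approx(5.0)
        assert bool(table.loc["a", "phase_missing"])

    def test_threshold_rule_on_phase_average(self):
        df = self._points(
            [["a", "pre", 0, 0, 4, 0], ["a", "post", 0, 0, 6.2, 0]]
        )
        table, _ = calibration_error(df)
        assert table.loc["a", "mean_error_deg"] == pytest.approx(5.1)
        assert not bool(table.loc["a", "included"])


def test_summarize_basics():
    s = summarize([1.0, 2.0, 3.0, 4.0])
    assert s.M == pytest.approx(2.5)
    assert s.median == pytest.approx(2.5)
    assert s.range == (1.0, 4.0)
    assert s.n == 4
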