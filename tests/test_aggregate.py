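import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_histogram_mode, oracle_percentile
from dailygait.aggregate import (
    AggregationConfig,
    build_subject_summary,
    duration_category,
    duration_category_summary,
    max_bout_distance,
    mean_daily_steps,
    mode_estimate,
    percentile95,
)
from dailygait.bouts import summarize_bout
from dailygait.recording_io import DayRecord


def make_bout(start, n_steps, cadence, step_length, day_index=0):
    period = 60.0 / cadence
    times = list(start + period * np.arange(n_steps))
    return summarize_bout(times, [step_length] * (n_steps - 1), day_index=day_index)


def make_days(validity):
    return [
        DayRecord(date=date(2021, 6, 1 + i), wear_hours=20.0 if v else 10.0, is_valid=v, day_index=i)
        for i, v in enumerate(validity)
    ]


class TestMeanDailySteps:
    def test_two_valid_days(self):
        bouts = [make_bout(0, 1000, 100, 0.6, 0), make_bout(5000, 2000, 100, 0.6, 1)]
        assert mean_daily_steps(bouts, make_days([True, True])) == pytest.approx(1500.0)

    def test_invalid_day_excluded(self):
        bouts = [
            make_bout(0, 1000, 100, 0.6, 0),
            make_bout(5000, 2000, 100, 0.6, 1),
            make_bout(9000, 5000, 100, 0.6, 2),
        ]
        days = make_days([True, True, False])
        assert mean_daily_steps(bouts, days) == pytest.approx(1500.0)

    def test_empty_valid_day_counts_zero(self):
        bouts = [make_bout(0, 1000, 100, 0.6, 0)]
        assert mean_daily_steps(bouts, make_days([True, True])) == pytest.approx(500.0)

    def test_no_valid_days_missing(self):
        assert math.isnan(mean_daily_steps([make_bout(0, 10, 100, 0.6, 0)], make_days([False])))

    def test_interval_convention(self):
        bouts = [make_bout(0, 10, 100, 0.6, 0)]
        assert mean_daily_steps(bouts, make_days([True]), steps_per_bout="n_intervals") == 9.0


class TestPercentile95:
    def test_one_to_hundred(self):
        assert percentile95(np.arange(1.0, 101.0)) == pytest.approx(95.05)

    def test_constant(self):
        assert percentile95([3.3] * 7) == pytest.approx(3.3)

    def test_single_value(self):
        assert percentile95([1.7]) == pytest.approx(1.7)

    def test_empty_missing(self):
        assert math.isnan(percentile95([]))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=1, max_size=40))
    def test_against_sort_oracle(self, values):
        assert percentile95(values) == pytest.approx(oracle_percentile(values, 95.0), abs=1e-9)


class TestModeEstimate:
    def test_binning_convention(self):
        assert mode_estimate([1.0, 1.0, 2.0], 1.0) == pytest.approx(1.5)

    def test_constant(self):
        assert mode_estimate([4.0] * 5, 1.0) == pytest.approx(4.5)

    def test_empty_missing(self):
        assert math.isnan(mode_estimate([], 1.0))

    def test_tie_breaks_lower(self):
        assert mode_estimate([1.2, 3.2], 1.0) == pytest.approx(1.5)

    def test_unimodal_recovery(self, rng):
        draws = rng.normal(5.0, 1.0, 10_000)
        draws = draws[draws > 0]
        est = mode_estimate(draws, 0.5)
        assert abs(est - 5.0) <= 1.0  # within one bin of the true mode

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.01, max_value=50), min_size=1, max_size=30))
    def test_against_histogram_oracle(self, values):
        assert mode_estimate(values, 0.25) == pytest.approx(
            oracle_histogram_mode(values, 0.25), abs=1e-9
        )

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            mode_estimate([1.0], 0.0)


class TestDurationCategories:
    def test_one_per_category(self):
        durations = [5.0, 15.0, 45.0, 90.0]
        bouts = []
        for i, d in enumerate(durations):
            n = int(d * 2) + 1  # cadence 120 -> 0.5 s period
            bouts.append(make_bout(i * 200.0, n, 120, 0.5))
        props, minutes = duration_category_summary(bouts)
        assert props == pytest.approx((0.25, 0.25, 0.25, 0.25))
        assert minutes == pytest.approx((5 / 60, 15 / 60, 45 / 60, 90 / 60))

    @pytest.mark.parametrize(
        "duration,expected", [(5.0, 0), (10.0, 0), (10.5, 1), (30.0, 1), (45.0, 2), (60.0, 2), (61.0, 3)]
    )
    def test_boundaries_left_closed(self, duration, expected):
        assert duration_category(duration) == expected

    def test_empty_bouts(self):
        props, minutes = duration_category_summary([])
        assert all(math.isnan(p) for p in props)
        assert minutes == (0.0, 0.0, 0.0, 0.0)

    def test_minutes_conservation(self, rng):
        bouts = [
            make_bout(i * 300.0, int(rng.integers(2, 200)), 120, 0.5) for i in range(40)
        ]
        _, minutes = duration_category_summary(bouts)
        assert sum(minutes) == pytest.approx(sum(b.duration for b in bouts) / 60.0, rel=1e-12)


class TestMaxBoutDistance:
    def test_maximum(self):
        bouts = [make_bout(0, 11, 120, d / 5 / 2) for d in (3.0, 72.0, 15.0)]
        dists = [b.distance for b in bouts]
        assert max_bout_distance(bouts) == pytest.approx(max(dists))

    def test_empty_missing(self):
        assert math.isnan(max_bout_distance([]))


class TestSubjectSummary:
    def test_constant_week(self):
        bouts = [make_bout(i * 100.0, 30, 100.0, 0.6, day_index=i % 7) for i in range(35)]
        days = make_days([True] * 7)
        s = build_subject_summary(bouts, days)
        assert abs(s.habitual_cadence - 100.0) <= 2.0
        assert abs(s.habitual_speed - 1.0) <= 0.05
        assert s.n_bouts == 35
        assert s.n_valid_days == 7
        assert sum(s.cat_proportions) == pytest.approx(1.0)

    def test_empty_bouts(self):
        s = build_subject_summary([], make_days([True]))
        assert s.n_bouts == 0
        assert math.isnan(s.fast_cadence)
        assert math.isnan(s.max_bout_distance)
        assert s.mean_daily_steps == 0.0  # one valid day with no walking

    def test_single_bout_fast_equals_habitual_neighborhood(self):
        b = make_bout(0, 20, 100.0, 0.6)
        s = build_subject_summary([b], make_days([True]))
        assert s.fast_cadence == pytest.approx(b.cadence)
        assert s.fast_speed == pytest.approx(b.speed)
        # mode of a single value is its bin midpoint
        assert abs(s.habitual_cadence - b.cadence) <= 1.0
        assert abs(s.habitual_speed - b.speed) <= 0.025 + 1e-9

    def test_order_invariance(self, rng):
        bouts = [
            make_bout(i * 120.0, int(rng.integers(5, 60)), float(rng.uniform(70, 130)),
                      float(rng.uniform(0.3, 0.8)), day_index=int(rng.integers(0, 7)))
            for i in range(30)
        ]
        days = make_days([True] * 7)
        s1 = build_subject_summary(bouts, days)
        s2 = build_subject_summary(list(reversed(bouts)), days)
        assert s1.mean_daily_steps == pytest.approx(s2.mean_daily_steps)
        assert s1.fast_cadence == pytest.approx(s2.fast_cadence)
        assert s1.habitual_cadence == pytest.approx(s2.habitual_cadence)
        assert s1.fast_speed == pytest.approx(s2.fast_speed)
        assert s1.habitual_speed == pytest.approx(s2.habitual_speed)
        assert s1.max_bout_distance == pytest.approx(s2.max_bout_distance)
        assert s1.cat_proportions == pytest.approx(s2.cat_proportions)
        assert s1.cat_minutes == pytest.approx(s2.cat_minutes)
        assert (s1.n_valid_days, s1.n_bouts) == (s2.n_valid_days, s2.n_bouts)

    def test_invalid_day_only_affects_daily_steps(self):
        bouts = [
            make_bout(0, 40, 100, 0.6, 0),
            make_bout(300, 80, 110, 0.7, 1),
        ]
        all_valid = build_subject_summary(bouts, make_days([True, True]))
        one_invalid = build_subject_summary(bouts, make_days([True, False]))
        assert one_invalid.mean_daily_steps != all_valid.mean_daily_steps
        assert one_invalid.fast_cadence == all_valid.fast_cadence
        assert one_invalid.max_bout_distance == all_valid.max_bout_distance
        assert one_invalid.cat_minutes == all_valid.cat_minutes
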