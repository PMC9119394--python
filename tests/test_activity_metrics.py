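"""Intensity classification, daily summaries, bout detection and w50."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_minute_frame, make_series
from lockstep.activity_metrics import (
    CUTPOINTS,
    Bout,
    IntensityCategory,
    NoBoutsError,
    classify_minute,
    classify_minutes,
    daily_summary,
    detect_bouts,
    usual_bout_duration,
    w50,
)
from lockstep.waking_filter import define_waking_minutes, split_into_days


def _one_day(frame):
    (day,) = split_into_days(define_waking_minutes(make_series(frame)), 0)
    return day


class TestClassifyMinute:
    @pytest.mark.parametrize(
        "mets, expected",
        [
            (0.0, IntensityCategory.SEDENTARY),
            (1.0, IntensityCategory.SEDENTARY),
            (1.4999, IntensityCategory.SEDENTARY),
            (1.5, IntensityCategory.LIGHTLY_ACTIVE),
            (2.9, IntensityCategory.LIGHTLY_ACTIVE),
            (3.0, IntensityCategory.FAIRLY_ACTIVE),
            (4.5, IntensityCategory.FAIRLY_ACTIVE),
            (6.0, IntensityCategory.VERY_ACTIVE),
            (11.0, IntensityCategory.VERY_ACTIVE),
        ],
    )
    def test_cutpoint_partition(self, mets, expected):
        assert classify_minute(mets) is expected

    def test_negative_mets_rejected(self):
        with pytest.raises(ValueError):
            classify_minute(-0.1)
        with pytest.raises(ValueError):
            classify_minutes(np.array([1.0, -2.0]))

    @given(st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partition_is_exhaustive_and_exclusive(self, mets):
        cat = classify_minute(mets)
        lows = (0.0,) + CUTPOINTS
        highs = CUTPOINTS + (np.inf,)
        idx = cat.code
        assert lows[idx] <= mets < highs[idx]


class TestDailySummary:
    def test_hand_summation(self, calendar):
        frame = make_minute_frame(
            "2020-03-01 08:00", 3, steps=[0, 30, 160], mets=[1.0, 2.0, 7.0], heart_rate=80
        )
        s = daily_summary(_one_day(frame), calendar)
        assert s.steps_per_day == 190
        assert s.mets_per_day == pytest.approx(10.0)
        assert s.minutes_per_category == {
            IntensityCategory.SEDENTARY: 1,
            IntensityCategory.LIGHTLY_ACTIVE: 1,
            IntensityCategory.FAIRLY_ACTIVE: 0,
            IntensityCategory.VERY_ACTIVE: 1,
        }
        assert s.lockdown == 0

    def test_all_sedentary_day(self, calendar):
        frame = make_minute_frame("2020-03-01 08:00", 600, mets=1.2, heart_rate=80)
        s = daily_summary(_one_day(frame), calendar)
        assert s.minutes_per_category[IntensityCategory.SEDENTARY] == 600
        assert sum(s.minutes_per_category.values()) == s.wear_minutes == 600

    def test_lockdown_indicator_on_after_cutoff(self, calendar):
        frame = make_minute_frame("2020-03-23 08:00", 5, heart_rate=80)
        assert daily_summary(_one_day(frame), calendar).lockdown == 1


class TestDetectBouts:
    def test_run_length_encoding(self):
        frame = make_minute_frame(
            "2020-03-01 08:00", 4, mets=[1.0, 1.0, 2.0, 1.0], heart_rate=80
        )
        bouts = detect_bouts(_one_day(frame))
        assert [(b.category, b.duration_min) for b in bouts] == [
            (IntensityCategory.SEDENTARY, 2),
            (IntensityCategory.LIGHTLY_ACTIVE, 1),
            (IntensityCategory.SEDENTARY, 1),
        ]

    def test_uniform_block_is_one_bout(self):
        frame = make_minute_frame("2020-03-01 08:00", 45, mets=1.0, heart_rate=80)
        bouts = detect_bouts(_one_day(frame))
        assert len(bouts) == 1 and bouts[0].duration_min == 45

    def test_gap_terminates_bout(self):
        frame = pd.concat(
            [
                make_minute_frame("2020-03-01 08:00", 2, mets=1.0, heart_rate=80),
                make_minute_frame("2020-03-01 08:03", 1, mets=1.0, heart_rate=80),
            ],
            ignore_index=True,
        )
        bouts = detect_bouts(_one_day(frame))
        assert [b.duration_min for b in bouts] == [2, 1]
        assert all(b.category is IntensityCategory.SEDENTARY for b in bouts)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bout_minutes_conserve_category_minutes(self, seed):
        from lockstep.data_io import LockdownCalendar

        calendar = LockdownCalendar(date(2020, 3, 23))
        rng = np.random.default_rng(seed)
        n = 300
        frame = make_minute_frame(
            "2020-03-01 08:00",
            n,
            mets=rng.choice([1.0, 2.0, 4.0, 7.0], n).tolist(),
            heart_rate=rng.choice([0, 80], n, p=[0.15, 0.85]).tolist(),
        )
        filtered = define_waking_minutes(make_series(frame))
        if len(filtered.records) == 0:
            return
        (day,) = split_into_days(filtered, 0)
        summary = daily_summary(day, calendar)
        per_cat: dict[IntensityCategory, int] = {c: 0 for c in IntensityCategory}
        for b in detect_bouts(day):
            per_cat[b.category] += b.duration_min
        assert per_cat == summary.minutes_per_category


def _w50_oracle(durations):
    """Independent cumulative-weight enumeration of the weighted median."""
    total = sum(durations)
    acc = 0.0
    for d in sorted(durations):
        acc += d
        if acc / total >= 0.5:
            return float(d)
    raise AssertionError("unreachable")


class TestUsualBoutDuration:
    @pytest.mark.parametrize(
        "durations, expected",
        [
            ([1, 1, 1, 1, 6], 6.0),  # cumulative fractions 0.1..0.4 then 1.0
            ([5, 5, 5], 5.0),  # degenerate: all bouts equal
            ([1, 2, 3], 2.0),  # cumulative hits exactly 0.5 at the 2-min bout
        ],
    )
    def test_known_values(self, durations, expected):
        assert w50(durations) == expected

    def test_no_bouts_is_undefined_not_zero(self):
        with pytest.raises(NoBoutsError):
            w50([])
        with pytest.raises(NoBoutsError):
            usual_bout_duration([], IntensityCategory.SEDENTARY)

    def test_filters_to_requested_category(self):
        ts = pd.Timestamp("2020-03-01 08:00")
        bouts = [
            Bout(IntensityCategory.SEDENTARY, ts, 10),
            Bout(IntensityCategory.LIGHTLY_ACTIVE, ts, 99),
            Bout(IntensityCategory.SEDENTARY, ts, 30),
        ]
        ubd = usual_bout_duration(bouts, IntensityCategory.SEDENTARY)
        assert ubd.w50 == 30.0 and ubd.total_category_minutes == 40

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=50))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, durations):
        assert w50(durations) == _w50_oracle(durations)

    @given(st.lists(st.integers(1, 200), min_size=1, max_size=40), st.randoms())
    @settings(max_examples=100, deadline=None)
    def test_order_and_split_invariance(self, durations, rnd):
        shuffled = list(durations)
        rnd.shuffle(shuffled)
        assert w50(shuffled) == w50(durations)
        k = rnd.randrange(len(durations) + 1)
        assert w50(durations[:k] + durations[k:]) == w50(durations)

    @given(st.lists(st.integers(1, 200), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance(self, durations):
        assert w50([2 * d for d in durations]) == 2 * w50(durations)
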