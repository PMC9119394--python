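"""Intensity classification, daily aggregation, bout detection and the w50 statistic.

Every worn waking minute carries a MET (metabolic equivalent task) value assigned
by the tracker; minutes are classified into four intensity categories by fixed MET
cutpoints, summed into per-day totals, and grouped into *bouts* — maximal runs of
consecutive minutes sharing a category.  The *usual bout duration* (w50, also
written x50) of a category is the duration-weighted median bout length: half of
all time spent in that category accrues in bouts longer than w50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityCategory",
    "CUTPOINTS",
    "DailySummary",
    "Bout",
    "UsualBoutDuration",
    "NoBoutsError",
    "classify_minute",
    "classify_minutes",
    "daily_summary",
    "daily_summaries",
    "detect_bouts",
    "bouts_for_series",
    "usual_bout_duration",
    "w50",
]


class IntensityCategory(str, Enum):
    """The four device-assigned intensity bands.

    Cutpoints on the MET scale: sedentary < 1.5, lightly_active [1.5, 3),
    fairly_active [3, 6), very_active >= 6.  The intervals are left-closed so
    that together they partition [0, inf); a MET value of exactly 6.0 is
    classified very_active.
    """

    SEDENTARY = "sedentary"
    LIGHTLY_ACTIVE = "lightly_active"
    FAIRLY_ACTIVE = "fairly_active"
    VERY_ACTIVE = "very_active"

    @property
    def code(self) -> int:
        return _CATEGORY_ORDER.index(self)


_CATEGORY_ORDER: tuple[IntensityCategory, ...] = (
    IntensityCategory.SEDENTARY,
    IntensityCategory.LIGHTLY_ACTIVE,
    IntensityCategory.FAIRLY_ACTIVE,
    IntensityCategory.VERY_ACTIVE,
)

#: MET thresholds between successive categories (left-closed intervals).
CUTPOINTS: tuple[float, float, float] = (1.5, 3.0, 6.0)


def classify_minute(mets: float) -> IntensityCategory:
    """Classify a single minute's MET value into an intensity category.

    Raises ``ValueError`` for negative METs (the MET scale starts at rest = 1,
    and the device never reports below 0).
    """
    if mets < 0:
        raise ValueError(f"MET value must be non-negative, got {mets}")
    return _CATEGORY_ORDER[int(np.searchsorted(CUTPOINTS, mets, side="right"))]


def classify_minutes(mets: np.ndarray) -> np.ndarray:
    """Vectorised classification: MET array -> integer category codes 0..3."""
    mets = np.asarray(mets)
    if mets.size and mets.min() < 0:
        raise ValueError("MET values must be non-negative")
    return np.searchsorted(CUTPOINTS, mets, side="right")


@dataclass
class DailySummary:
    """Per-day activity totals over retained (worn, waking) minutes."""

    date: date
    steps_per_day: int
    mets_per_day: float
    minutes_per_category: dict[IntensityCategory, int]
    lockdown: int
    wear_minutes: int = 0

    def __post_init__(self) -> None:
        if self.steps_per_day < 0 or self.mets_per_day < 0:
            raise ValueError("daily steps and METs must be non-negative")


@dataclass(frozen=True)
class Bout:
    """A maximal run of consecutive retained minutes in one category."""

    category: IntensityCategory
    start: datetime
    duration_min: int

    def __post_init__(self) -> None:
        if self.duration_min < 1:
            raise ValueError("bout duration must be >= 1 minute")


@dataclass(frozen=True)
class UsualBoutDuration:
    category: IntensityCategory
    w50: float
    total_category_minutes: int


class NoBoutsError(ValueError):
    """Raised when w50 is requested for a category with no bouts (undefined)."""


def daily_summary(day, calendar) -> DailySummary:
    """Aggregate one waking day into totals and per-category minute tallies.

    ``day`` is a :class:`~lockstep.waking_filter.WakingDay`; ``calendar`` a
    :class:`~lockstep.data_io.LockdownCalendar` supplying the 0/1 interruption
    indicator for the day's date.
    """
    df = day.minutes
    if len(df) == 0:
        raise ValueError("daily_summary requires at least one retained minute")
    codes = classify_minutes(df["mets"].to_numpy())
    counts = np.bincount(codes, minlength=4)
    return DailySummary(
        date=day.date,
        steps_per_day=int(df["steps"].sum()),
        mets_per_day=float(df["mets"].sum()),
        minutes_per_category={c: int(counts[c.code]) for c in _CATEGORY_ORDER},
        lockdown=calendar.indicator(day.date),
        wear_minutes=int(len(df)),
    )


def daily_summaries(days: Iterable, calendar) -> pd.DataFrame:
    """Tabulate :func:`daily_summary` over many days.

    Columns: date, steps, mets, sedentary_min, light_min, fair_min, very_min,
    wear_minutes, lockdown.  This is the frame the daily models consume.
    """
    rows = []
    for day in days:
        s = daily_summary(day, calendar)
        m = s.minutes_per_category
        rows.append(
            (
                s.date,
                s.steps_per_day,
                s.mets_per_day,
                m[IntensityCategory.SEDENTARY],
                m[IntensityCategory.LIGHTLY_ACTIVE],
                m[IntensityCategory.FAIRLY_ACTIVE],
                m[IntensityCategory.VERY_ACTIVE],
                s.wear_minutes,
                s.lockdown,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "date",
            "steps",
            "mets",
            "sedentary_min",
            "light_min",
            "fair_min",
            "very_min",
            "wear_minutes",
            "lockdown",
        ],
    )


def detect_bouts(day) -> list[Bout]:
    """Run-length encode a waking day's minutes into maximal category bouts.

    Minutes must be consecutive in wall-clock time to extend a bout: a gap of
    one or more removed/missing minutes terminates the run, as does the day
    boundary (bouts never bridge nonwear or span days).
    """
    df = day.minutes
    if len(df) == 0:
        return []
    ts = df["timestamp"].to_numpy().astype("datetime64[m]")
    codes = classify_minutes(df["mets"].to_numpy())
    # A new bout starts where the category changes or the clock jumps.
    gap = np.diff(ts.astype(np.int64)) != 1
    change = np.diff(codes) != 0
    starts = np.concatenate(([True], gap | change))
    start_idx = np.flatnonzero(starts)
    lengths = np.diff(np.append(start_idx, len(df)))
    return [
        Bout(
            category=_CATEGORY_ORDER[int(codes[i])],
            start=pd.Timestamp(ts[i]).to_pydatetime(),
            duration_min=int(n),
        )
        for i, n in zip(start_idx, lengths)
    ]


def bouts_for_series(days: Iterable) -> list[Bout]:
    """Concatenate bouts over a participant's waking days."""
    out: list[Bout] = []
    for day in days:
        out.extend(detect_bouts(day))
    return out


def w50(durations: Sequence[float] | np.ndarray) -> float:
    """Duration-weighted median of bout durations.

    Bouts are sorted ascending by duration; cumulative duration is accumulated
    as a fraction of the total; w50 is the duration of the first bout at which
    the cumulative fraction reaches >= 0.5 (the attained value — no
    interpolation, so a fraction landing exactly on 0.5 selects that bout).
    """
    d = np.sort(np.asarray(durations, dtype=float))
    if d.size == 0:
        raise NoBoutsError("w50 is undefined for an empty bout set")
    frac = np.cumsum(d) / d.sum()
    return float(d[int(np.argmax(frac >= 0.5))])


def usual_bout_duration(bouts: Sequence[Bout], category: IntensityCategory) -> UsualBoutDuration:
    """w50 for one category over a set of bouts.

    Raises :class:`NoBoutsError` if the category has no bouts — the statistic
    is undefined, never zero.
    """
    durations = [b.duration_min for b in bouts if b.category == category]
    if not durations:
        raise NoBoutsError(f"no bouts of category {category.value}")
    return UsualBoutDuration(
        category=category,
        w50=w50(durations),
        total_category_minutes=int(sum(durations)),
    )
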