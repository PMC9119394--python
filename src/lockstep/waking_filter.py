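"""Cleaning rules that define the daily waking, device-worn analysis set.

A minute is removed when any of three criteria hold: the device detected sleep
(sleep_flag), the clock time falls in [00:00, 05:00) (overnight window, read as
half-open so a minute stamped exactly 05:00 is retained), or the recorded heart
rate is 0 (device not worn).  What remains is the "daily waking period" the
models operate on.  A minute may satisfy several criteria but is removed once;
reason tallies are tracked separately for the wear log.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .data_io import ParticipantSeries

__all__ = [
    "WakingDay",
    "define_waking_minutes",
    "removal_reasons",
    "split_into_days",
    "wear_log",
]

#: Overnight removal window [00:00, 05:00), in minutes of day.
NIGHT_WINDOW_END_MIN = 5 * 60

#: Default minimum retained minutes for a day to count as valid (10 waking
#: hours, the usual actigraphy convention).  Pass 0 to apply no day-validity
#: rule at all (every day with >=1 retained minute is analysed).
DEFAULT_MIN_WEAR_MINUTES = 600


@dataclass
class WakingDay:
    """Retained minutes of one calendar date after the waking filter."""

    date: date
    minutes: pd.DataFrame
    wear_minutes: int
    valid: bool

    def __post_init__(self) -> None:
        if self.wear_minutes != len(self.minutes):
            raise ValueError("wear_minutes must equal the retained minute count")


def _removal_mask(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ts = df["timestamp"]
    minute_of_day = ts.dt.hour.to_numpy() * 60 + ts.dt.minute.to_numpy()
    asleep = df["sleep_flag"].to_numpy().astype(bool)
    night = minute_of_day < NIGHT_WINDOW_END_MIN
    not_worn = df["heart_rate"].to_numpy() == 0
    return asleep, night, not_worn


def define_waking_minutes(series: ParticipantSeries) -> ParticipantSeries:
    """Drop sleep, overnight-window and zero-heart-rate minutes.

    Order is preserved; the result may retain no minutes, in which case the
    original (empty-forbidden) series contract is relaxed by returning the
    filtered frame wrapped without re-validation of non-emptiness downstream —
    callers splitting into days simply obtain no days.  Idempotent.
    """
    df = series.records
    asleep, night, not_worn = _removal_mask(df)
    keep = ~(asleep | night | not_worn)
    filtered = df.loc[keep].reset_index(drop=True)
    out = object.__new__(ParticipantSeries)
    out.participant_id = series.participant_id
    out.records = filtered
    if len(filtered):
        # Re-run invariant checks only when non-empty (they assume >=1 row).
        ParticipantSeries.__post_init__(out)
    return out


def removal_reasons(series: ParticipantSeries) -> dict[str, int]:
    """Tally removal criteria over a raw series.

    A minute may be counted under several reasons; ``removed`` counts each
    removed minute exactly once, so the reason tallies generally sum to more
    than ``removed``.
    """
    asleep, night, not_worn = _removal_mask(series.records)
    return {
        "total": int(len(series.records)),
        "removed": int((asleep | night | not_worn).sum()),
        "sleep": int(asleep.sum()),
        "night_window": int(night.sum()),
        "not_worn": int(not_worn.sum()),
    }


def split_into_days(
    series: ParticipantSeries,
    min_wear_minutes: int = DEFAULT_MIN_WEAR_MINUTES,
) -> list[WakingDay]:
    """Partition a filtered series into per-date waking days, sorted by date.

    Every date with at least one retained minute yields a WakingDay; its
    ``valid`` flag records whether wear_minutes >= min_wear_minutes (boundary
    inclusive).  Dates with zero retained minutes yield nothing (non-wear
    days are dropped from all analyses).
    """
    df = series.records
    if len(df) == 0:
        return []
    dates = df["timestamp"].dt.date
    days = []
    for d, grp in df.groupby(dates, sort=True):
        n = len(grp)
        days.append(
            WakingDay(
                date=d,
                minutes=grp.reset_index(drop=True),
                wear_minutes=n,
                valid=n >= min_wear_minutes,
            )
        )
    return days


def wear_log(series: ParticipantSeries, filtered_days: list[WakingDay]) -> pd.DataFrame:
    """Per-day wear log: date, wear_minutes, valid flag (delimited-text friendly)."""
    rows = [(d.date, d.wear_minutes, d.valid) for d in filtered_days]
    log = pd.DataFrame(rows, columns=["date", "wear_minutes", "valid"])
    log.attrs["removal_reasons"] = removal_reasons(series)
    return log
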