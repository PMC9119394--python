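"""Shared fixtures: small hand-built minute frames and a fixed cutoff calendar."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from lockstep.data_io import MINUTE_COLUMNS, LockdownCalendar, ParticipantSeries

CUTOFF = date(2020, 3, 23)


def make_minute_frame(
    start: str,
    n: int,
    steps: int | list = 0,
    mets: float | list = 1.0,
    heart_rate: int | list = 80,
    sleep_flag: bool | list = False,
) -> pd.DataFrame:
    """n consecutive minutes starting at `start`, with scalar or per-minute values."""

    def expand(v):
        return np.resize(v, n) if np.ndim(v) else np.full(n, v)

    return pd.DataFrame(
        {
            "timestamp": pd.date_range(start, periods=n, freq="min"),
            "steps": expand(steps).astype(np.int64),
            "mets": expand(mets).astype(float),
            "heart_rate": expand(heart_rate).astype(np.int64),
            "sleep_flag": expand(sleep_flag).astype(bool),
        },
        columns=list(MINUTE_COLUMNS),
    )


def make_series(frame_or_frames, participant_id: str = "P01") -> ParticipantSeries:
    if isinstance(frame_or_frames, list):
        frame = pd.concat(frame_or_frames, ignore_index=True)
    else:
        frame = frame_or_frames
    return ParticipantSeries(participant_id, frame)


@pytest.fixture
def calendar() -> LockdownCalendar:
    return LockdownCalendar(CUTOFF)
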