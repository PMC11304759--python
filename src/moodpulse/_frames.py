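"""Shared time-frame conventions.

Every module works on half-open 3-hour frames [t, t+3h) anchored at local
midnight, so a day has 8 slots starting at 00:00, 03:00, ..., 21:00.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

FRAME_HOURS = 3
SLOTS_PER_DAY = 24 // FRAME_HOURS

# ESM prompt hours (six notifications per day, ~8 AM through 6 PM)
PROMPT_HOURS = (8, 10, 12, 14, 16, 18)


def frame_floor(timestamps) -> pd.Series:
    """Floor timestamps to the start of their 3-hour frame."""
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
    return ts.dt.floor(f"{FRAME_HOURS}h")


def slot_times(start_date: dt.date, n_days: int) -> pd.DatetimeIndex:
    """Frame-start timestamps for ``n_days`` days from local midnight of start_date."""
    start = pd.Timestamp(start_date)
    return pd.date_range(start, periods=n_days * SLOTS_PER_DAY, freq=f"{FRAME_HOURS}h")


def slot_index(timestamps, start_date: dt.date) -> np.ndarray:
    """Map timestamps to integer slot indices relative to start_date midnight."""
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
    delta = ts - pd.Timestamp(start_date)
    return (delta.dt.total_seconds() // (FRAME_HOURS * 3600)).astype(int).to_numpy()
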