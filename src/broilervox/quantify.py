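"""From probability rasters to vocalization durations and time bins.

The headline quantity of acoustic broiler monitoring is seconds of each
vocalization type per minute (s/min): prediction rows whose class score
reaches the 0.7 probability threshold are counted and multiplied by the
240 ms frame duration, per wall-clock minute.  Because rows are normalized
and 0.7 > 0.5, at most one class can exceed the threshold per row, so the
per-minute type durations sum to at most 60 s.  Minutes are averaged into
hourly means, and hours map onto the four diurnal bins -- night (22-04),
morning (04-10), midday (10-16), evening (16-22) -- while bird age maps
onto the production phases starter (days 0-9), grower (10-22), finisher
(23-41).  Bin edges are half-open [start, end).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calls import FRAME_SECONDS, VOCAL_LABELS, RASTER_CLASSES
from .recognizer import ProbabilityRaster

__all__ = [
    "DEFAULT_THRESHOLD",
    "threshold_durations",
    "aggregate_hourly",
    "aggregate_bins",
    "bin_time_of_day",
    "assign_phase",
    "DIURNAL_BINS",
    "PHASES",
]

DEFAULT_THRESHOLD = 0.7

#: Half-open hour ranges of the diurnal bins (night wraps midnight).
DIURNAL_BINS = {
    "night": ((22, 24), (0, 4)),
    "morning": ((4, 10),),
    "midday": ((10, 16),),
    "evening": ((16, 22),),
}

#: Production phases by age in days (inclusive ranges).
PHASES = {"starter": (0, 9), "grower": (10, 22), "finisher": (23, 41)}


def threshold_durations(
    raster: ProbabilityRaster, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Seconds of each vocalization type per minute from a raster.

    A row counts toward a type when its score is >= ``threshold``
    (inclusive); counted rows are multiplied by the 0.24 s frame duration.
    Rows are assigned to the minute containing their start time (raster
    start clock, or minute 0 when none).  Background is not reported.
    Rasters whose rows do not sum to 1 are rejected.
    """
    scores = np.asarray(raster.scores, dtype=float)
    if scores.size and np.max(np.abs(scores.sum(axis=1) - 1.0)) > 1e-3:
        raise ValueError("raster rows must sum to 1")
    t0 = raster.start_clock or 0.0
    n = scores.shape[0]
    times = t0 + raster.frame_duration * np.arange(n)
    minutes = np.floor(times / 60.0).astype(int) if n else np.zeros(0, dtype=int)
    index = pd.RangeIndex(0, 1, name="minute") if n == 0 else pd.RangeIndex(
        minutes.min(), minutes.max() + 1, name="minute"
    )
    out = pd.DataFrame(0.0, index=index, columns=list(VOCAL_LABELS))
    for label in VOCAL_LABELS:
        col = RASTER_CLASSES.index(label)
        hits = scores[:, col] >= threshold
        if hits.any():
            counts = pd.Series(minutes[hits]).value_counts()
            out.loc[counts.index, label] += counts.to_numpy() * raster.frame_duration
    return out


def aggregate_hourly(minutes: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic hourly mean of per-minute durations (s/min).

    Only recorded minutes enter the denominator; hours with no minutes are
    simply absent (missing, never zero -- zeros would bias diurnal means).
    """
    if minutes.empty:
        raise ValueError("no minutes to aggregate")
    hours = minutes.index.to_numpy() // 60
    agg = minutes.groupby(hours).mean()
    agg.index.name = "hour"
    return agg


def aggregate_bins(hourly: pd.DataFrame) -> pd.DataFrame:
    """Mean s/min per diurnal bin from an hourly table (index = hour;
    clock hour is taken modulo 24)."""
    if hourly.empty:
        raise ValueError("no hours to aggregate")
    labels = [bin_time_of_day(int(h) % 24) for h in hourly.index]
    out = hourly.groupby(labels).mean()
    out.index.name = "bin"
    return out


def bin_time_of_day(hour_of_day: int) -> str:
    """Map a clock hour (0-23) to its diurnal bin."""
    h = int(hour_of_day)
    if not 0 <= h <= 23:
        raise ValueError(f"hour {hour_of_day} outside 0-23")
    for name, ranges in DIURNAL_BINS.items():
        if any(lo <= h < hi for lo, hi in ranges):
            return name
    raise AssertionError("unreachable: bins partition the clock")


def assign_phase(age_days: float) -> str:
    """Map bird age in days to the production phase."""
    d = float(age_days)
    if not 0 <= d <= 41:
        raise ValueError(f"age {age_days} outside 0-41 days")
    for name, (lo, hi) in PHASES.items():
        if lo <= d < hi + 1:
            return name
    raise AssertionError("unreachable: phases partition 0-41")
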