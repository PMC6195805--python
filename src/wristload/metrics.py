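"""Daily accelerometer metrics from a 5-s ENMO epoch series.

Average Acceleration (mean wear-time ENMO), Most Active-30mins (best
contiguous 30-minute window mean), Mins>=400mg (time at or above the
vigorous threshold), 50-mg intensity-bin minutes between 50 and 4000 mg,
and the WL400-4000 workload composite (bin intensity x bin minutes).
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import EPOCH_S, EPOCHS_PER_MIN, DayMetrics, EpochSeries

#: 50-mg bin lower edges [50, 100, ..., 3950]; one extra overflow bin >= 4000.
BIN_EDGES = np.arange(50.0, 4000.0 + 50.0, 50.0)
N_BINS = len(BIN_EDGES)  # 79 regular bins + overflow = 80 values

VIGOROUS_THRESHOLD_MG = 400.0
MOST_ACTIVE_WINDOW_MIN = 30
_MINUTES_PER_EPOCH = EPOCH_S / 60.0


def average_acceleration(series: EpochSeries) -> float:
    """Mean ENMO over the day's wear epochs; NaN when nothing was worn."""
    worn = series.values[series.wear]
    if worn.size == 0:
        return float("nan")
    return float(worn.mean())


def most_active_30mins(series: EpochSeries, window_min: int = MOST_ACTIVE_WINDOW_MIN) -> float:
    """Highest mean ENMO over any contiguous fully-worn window.

    Windows advance one epoch at a time, must contain wear epochs only, and
    do not wrap across midnight. NaN when no qualifying window exists.
    """
    w = window_min * EPOCHS_PER_MIN
    if len(series) < w:
        return float("nan")
    windows = np.lib.stride_tricks.sliding_window_view(series.values, w)
    wear_counts = np.lib.stride_tricks.sliding_window_view(series.wear, w).sum(axis=1)
    valid = wear_counts == w
    if not valid.any():
        return float("nan")
    return float(windows[valid].mean(axis=1).max())


def mins_above(series: EpochSeries, threshold: float = VIGOROUS_THRESHOLD_MG) -> float:
    """Wear minutes with epoch ENMO at or above the threshold (inclusive)."""
    count = int(np.count_nonzero(series.values[series.wear] >= threshold))
    return count * _MINUTES_PER_EPOCH


def intensity_bin_minutes(series: EpochSeries) -> np.ndarray:
    """Minutes per 50-mg half-open bin [50,100) ... [3950,4000), plus overflow.

    Wear epochs below 50 mg are uncounted; epochs at or above 4000 mg land in
    the final overflow bin. Returns 80 values.
    """
    worn = series.values[series.wear]
    counts = np.zeros(N_BINS, dtype=np.int64)
    if worn.size:
        idx = np.searchsorted(BIN_EDGES, worn, side="right") - 1
        in_range = idx >= 0  # below 50 mg excluded
        idx = np.minimum(idx[in_range], N_BINS - 1)  # >= 4000 -> overflow
        np.add.at(counts, idx, 1)
    return counts * _MINUTES_PER_EPOCH


def workload(
    bin_minutes: np.ndarray,
    lower: float = 400.0,
    upper: float = 4000.0,
    representative: str = "midpoint",
) -> float:
    """Workload composite: sum of bin intensity x bin minutes, in mg-minutes.

    Bins with lower edge in [lower, upper) contribute; the overflow bin does
    not. The bin's representative intensity is its midpoint by default, with
    lower/upper-edge variants available.
    """
    bin_minutes = np.asarray(bin_minutes, dtype=float)
    if representative == "midpoint":
        rep = BIN_EDGES + 25.0
    elif representative == "lower":
        rep = BIN_EDGES.copy()
    elif representative == "upper":
        rep = BIN_EDGES + 50.0
    else:
        raise ValueError(f"unknown bin representative: {representative!r}")
    mask = (BIN_EDGES >= lower) & (BIN_EDGES < upper)
    return float(np.sum(rep[mask] * bin_minutes[: len(BIN_EDGES)][mask]))


def day_metrics(series: EpochSeries, workload_representative: str = "midpoint") -> DayMetrics:
    """All daily metrics for one epoch series."""
    bins = intensity_bin_minutes(series)
    return DayMetrics(
        participant_id=series.participant_id,
        date=series.date,
        wear_h=series.wear_hours,
        avg_accel=average_acceleration(series),
        most_active_30=most_active_30mins(series),
        mins_ge_400=mins_above(series),
        bin_minutes=bins,
        wl_400_4000=workload(bins, representative=workload_representative),
    )


def metrics_frame(metrics: Sequence[DayMetrics]) -> pd.DataFrame:
    """Flat per-day table of the scalar metrics (bin minutes excluded)."""
    return pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in metrics],
            "date": [m.date for m in metrics],
            "wear_h": [m.wear_h for m in metrics],
            "avg_accel": [m.avg_accel for m in metrics],
            "most_active_30": [m.most_active_30 for m in metrics],
            "mins_ge_400": [m.mins_ge_400 for m in metrics],
            "wl_400_4000": [m.wl_400_4000 for m in metrics],
        }
    )
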