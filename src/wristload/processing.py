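"""Raw-signal processing: autocalibration, ENMO epochs, wear detection.

Mirrors the open-source raw-accelerometry processing chain: an iterative
least-squares autocalibration against the 1-g sphere using stationary
windows, per-sample ENMO (vector magnitude minus 1000 mg, truncated at
zero) averaged over 5-s epochs, a variance/range non-wear heuristic, and a
minimum-wear valid-day filter.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    EPOCH_S,
    GRAVITY_MG,
    CalibrationParams,
    EpochSeries,
    RawSegment,
)

# stationary-window detection defaults
STATIONARY_WINDOW_S = 10.0
STATIONARY_SD_MG = 13.0
MIN_STATIONARY_WINDOWS = 3
MIN_ANGLE_DEG = 15.0

# non-wear heuristic defaults
NONWEAR_WINDOW_MIN = 60.0
NONWEAR_STEP_MIN = 15.0
NONWEAR_SD_MG = 13.0
NONWEAR_RANGE_MG = 50.0


def enmo_per_sample(xyz: np.ndarray) -> np.ndarray:
    """Per-sample ENMO in mg: max(0, |a| - 1000)."""
    return np.maximum(np.linalg.norm(xyz, axis=1) - GRAVITY_MG, 0.0)


def _window_starts(n: int, win: int, step: int) -> np.ndarray:
    if n < win:
        return np.empty(0, dtype=int)
    return np.arange(0, n - win + 1, step)


def stationary_window_means(
    raw: RawSegment,
    window_s: float = STATIONARY_WINDOW_S,
    sd_threshold: float = STATIONARY_SD_MG,
) -> np.ndarray:
    """Mean vectors of non-overlapping stationary windows, shape (k, 3).

    A window is stationary when all three axes have SD below the threshold.
    """
    win = int(round(window_s * raw.fs))
    xyz = raw.xyz
    means = []
    for i in _window_starts(len(raw), win, win):
        chunk = xyz[i : i + win]
        if np.all(chunk.std(axis=0) < sd_threshold):
            means.append(chunk.mean(axis=0))
    return np.asarray(means) if means else np.empty((0, 3))


def _n_diverse_orientations(means: np.ndarray, min_angle_deg: float = MIN_ANGLE_DEG) -> int:
    """Greedy count of window orientations with pairwise separation above the cutoff."""
    cos_max = np.cos(np.deg2rad(min_angle_deg))
    selected: List[np.ndarray] = []
    for v in means:
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        u = v / norm
        if all(float(u @ s) < cos_max for s in selected):
            selected.append(u)
    return len(selected)


def _sphere_error(means: np.ndarray, params: CalibrationParams) -> float:
    cal = params.apply(means)
    return float(np.mean(np.abs(np.linalg.norm(cal, axis=1) - GRAVITY_MG)))


def autocalibrate(
    raw: RawSegment,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CalibrationParams:
    """Estimate per-axis offset and scale from stationary windows.

    Iteratively regresses each axis of the stationary-window mean vectors
    onto its projection on the unit-gravity sphere until the mean absolute
    deviation of calibrated magnitudes from 1000 mg stops improving. Falls
    back to the identity calibration (with a warning and ``calibrated=False``)
    when fewer than three sufficiently distinct stationary orientations are
    available, or when the fit would not improve the error or leaves the
    plausible scale range.
    """
    means = stationary_window_means(raw)
    if len(means) < MIN_STATIONARY_WINDOWS or _n_diverse_orientations(means) < MIN_STATIONARY_WINDOWS:
        warnings.warn("autocalibration skipped: too few diverse stationary windows")
        err = _sphere_error(means, CalibrationParams()) if len(means) else float("nan")
        return CalibrationParams.identity(error=err, message="insufficient stationary data")

    identity = CalibrationParams()
    error_before = _sphere_error(means, identity)

    offset = np.zeros(3)
    scale = np.ones(3)
    prev_err = error_before
    for _ in range(max_iter):
        cal = means * scale + offset
        norms = np.linalg.norm(cal, axis=1)
        target = GRAVITY_MG * cal / norms[:, None]
        new_scale = np.empty(3)
        new_offset = np.empty(3)
        for axis in range(3):
            A = np.column_stack([means[:, axis], np.ones(len(means))])
            coef, *_ = np.linalg.lstsq(A, target[:, axis], rcond=None)
            new_scale[axis], new_offset[axis] = coef
        scale, offset = new_scale, new_offset
        err = _sphere_error(means, CalibrationParams(offset=offset, scale=scale))
        if abs(prev_err - err) < tol:
            break
        prev_err = err

    if err > error_before + 1e-9 or np.any(scale <= 0.5) or np.any(scale >= 1.5):
        warnings.warn("autocalibration rejected: fit did not improve or left plausible range")
        return CalibrationParams.identity(error=error_before, message="fit rejected")
    return CalibrationParams(
        offset=offset,
        scale=scale,
        error_before=error_before,
        error_after=min(err, error_before),  # numerically no-worse by construction
        calibrated=True,
    )


def compute_enmo_epochs(
    raw: RawSegment,
    calibration: Optional[CalibrationParams] = None,
    epoch_s: int = EPOCH_S,
    participant_id: str = "",
    date=None,
) -> EpochSeries:
    """Calibrate, compute per-sample ENMO, and average over fixed epochs.

    Truncation at zero happens per sample, before averaging; a trailing
    partial epoch is dropped rather than padded. An empty segment yields an
    empty series.
    """
    calibration = calibration if calibration is not None else CalibrationParams()
    n_per = int(round(epoch_s * raw.fs))
    n_full = len(raw) // n_per
    if n_full == 0:
        return EpochSeries(participant_id, date, np.empty(0), np.empty(0, dtype=bool))
    xyz = calibration.apply(raw.xyz[: n_full * n_per])
    enmo = enmo_per_sample(xyz)
    values = enmo.reshape(n_full, n_per).mean(axis=1)
    return EpochSeries(participant_id, date, values, np.ones(n_full, dtype=bool))


def detect_nonwear(
    raw: RawSegment,
    epoch_s: int = EPOCH_S,
    window_min: float = NONWEAR_WINDOW_MIN,
    step_min: float = NONWEAR_STEP_MIN,
    sd_threshold: float = NONWEAR_SD_MG,
    range_threshold: float = NONWEAR_RANGE_MG,
) -> np.ndarray:
    """Epoch-level wear mask from a sliding variance/range heuristic.

    60-minute windows evaluated every 15 minutes; a window whose per-axis SD
    and range fall below the thresholds on at least two of three axes marks
    every epoch it covers as non-wear.
    """
    n_per = int(round(epoch_s * raw.fs))
    n_epochs = len(raw) // n_per
    wear = np.ones(n_epochs, dtype=bool)
    win = int(round(window_min * 60 * raw.fs))
    step = int(round(step_min * 60 * raw.fs))
    xyz = raw.xyz
    starts = _window_starts(len(raw), win, step)
    if len(starts) == 0 and len(raw) > 0:
        starts = np.array([0])
        win = len(raw)
    for i in starts:
        chunk = xyz[i : i + win]
        sd = chunk.std(axis=0)
        rng_ = chunk.max(axis=0) - chunk.min(axis=0)
        if np.sum((sd < sd_threshold) & (rng_ < range_threshold)) >= 2:
            e0 = i // n_per
            e1 = int(np.ceil((i + win) / n_per))
            wear[e0 : min(e1, n_epochs)] = False
    return wear


def filter_valid_days(
    days: Sequence[EpochSeries],
    min_wear_h: float = 10.0,
    waking_window: Optional[Tuple[float, float]] = None,
) -> Tuple[List[EpochSeries], float]:
    """Drop days with wear time below the threshold; report retention.

    ``waking_window`` optionally restricts the wear count to a clock window
    given in hours, e.g. ``(6, 24)``; by default the full 24-h day counts.
    Removal is strict: a day with exactly ``min_wear_h`` hours is retained.
    """
    retained: List[EpochSeries] = []
    for day in days:
        wear = day.wear
        if waking_window is not None:
            lo = int(waking_window[0] * 3600 / EPOCH_S)
            hi = int(waking_window[1] * 3600 / EPOCH_S)
            wear = wear[lo:hi]
        if wear.sum() * EPOCH_S / 3600.0 >= min_wear_h:
            retained.append(day)
    fraction = len(retained) / len(days) if days else float("nan")
    return retained, fraction
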