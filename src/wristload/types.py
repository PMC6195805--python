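"""Shared domain types for the wristload pipeline.

Units follow the accelerometry convention used throughout the package:
acceleration in milli-g (mg, 1/1000 of standard gravity), epoch values are
5-second mean ENMO (Euclidean norm minus one g, truncated at zero), and
day-level times are minutes unless a field name says otherwise.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Gravity in milli-g; the ENMO reference magnitude.
GRAVITY_MG = 1000.0

#: Epoch length in seconds.
EPOCH_S = 5

#: Epochs per minute at 5-s epochs.
EPOCHS_PER_MIN = 60 // EPOCH_S

#: Epochs in a full midnight-to-midnight day.
EPOCHS_PER_DAY = 24 * 60 * EPOCHS_PER_MIN


@dataclass
class RawSegment:
    """One continuous bout of raw triaxial wrist acceleration.

    Parameters
    ----------
    timestamps : ndarray
        Sample times in seconds, strictly increasing, approximately uniform.
    x, y, z : ndarray
        Per-axis acceleration in milli-g, clipped to the +/-8000 mg range of
        the recording device.
    fs : float
        Declared sampling rate in Hz.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.timestamps)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("axis arrays and timestamps must share length")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array of the three axes."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class CalibrationParams:
    """Affine per-axis calibration: calibrated = raw * scale + offset."""

    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    error_before: float = float("nan")
    error_after: float = float("nan")
    calibrated: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)

    @classmethod
    def identity(cls, error: float = float("nan"), message: str = "") -> "CalibrationParams":
        return cls(
            offset=np.zeros(3),
            scale=np.ones(3),
            error_before=error,
            error_after=error,
            calibrated=False,
            message=message,
        )

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz * self.scale + self.offset


@dataclass
class EpochSeries:
    """Sequence of 5-s mean ENMO epochs with a wear mask.

    A full calendar day has exactly ``EPOCHS_PER_DAY`` (17,280) epochs aligned
    to midnight; segment-level series produced by the raw pipeline may be
    shorter.
    """

    participant_id: str
    date: _dt.date
    values: np.ndarray
    wear: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.values.shape != self.wear.shape:
            raise ValueError("values and wear mask must share shape")
        if self.values.size and self.values.min() < 0:
            raise ValueError("ENMO epoch values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def wear_hours(self) -> float:
        return float(self.wear.sum()) * EPOCH_S / 3600.0


@dataclass
class DayMetrics:
    """Daily accelerometer metrics for one participant-day.

    ``bin_minutes`` holds 79 half-open 50-mg bins [50,100) ... [3950,4000)
    followed by one overflow bin for epochs >= 4000 mg (80 values total).
    Undefined metrics (zero wear) are NaN, never zero.
    """

    participant_id: str
    date: _dt.date
    wear_h: float
    avg_accel: float
    most_active_30: float
    mins_ge_400: float
    bin_minutes: np.ndarray
    wl_400_4000: float

    def __post_init__(self) -> None:
        self.bin_minutes = np.asarray(self.bin_minutes, dtype=float)


@dataclass
class TrainingLogEntry:
    """One self-reported training session."""

    participant_id: str
    date: _dt.date
    start_time: _dt.time
    end_time: _dt.time
    activity: str
    miles: Optional[float]
    rpe: int

    @property
    def duration_min(self) -> float:
        start = self.start_time.hour * 60 + self.start_time.minute + self.start_time.second / 60
        end = self.end_time.hour * 60 + self.end_time.minute + self.end_time.second / 60
        return end - start


@dataclass
class DayLabel:
    """Training-log-derived classification of one participant-day."""

    participant_id: str
    date: _dt.date
    category: str  # running | other_training | rest
    other_activities: tuple = ()
    miles: float = 0.0
    duration: float = 0.0
    mean_rpe: float = float("nan")
    training_load: float = 0.0

    @property
    def is_running(self) -> bool:
        return self.category == "running"


CATEGORIES: Sequence[str] = ("running", "other_training", "rest")
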