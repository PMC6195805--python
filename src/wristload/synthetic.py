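"""Synthetic cohort generator.

Emulates a cohort of distance runners wearing a wrist accelerometer around
the clock: per-day 5-s ENMO epoch series, raw 100-Hz triaxial segments for
the signal-processing path, a matched (optionally noisy) training log, and
ground-truth day labels.

Intensity anchors for running (760 +/- 200 mg) and fast walking
(170 +/- 56 mg) follow published wrist-accelerometry reference values; the
remaining activity profiles are calibrated assumptions chosen to reproduce
the qualitative misclassification ordering seen in the field (field/racket
sport close to running, gym work well below it) and are fully configurable.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    EPOCH_S,
    EPOCHS_PER_DAY,
    EPOCHS_PER_MIN,
    GRAVITY_MG,
    DayLabel,
    EpochSeries,
    RawSegment,
    TrainingLogEntry,
)

MAX_ABS_MG = 8000.0  # device dynamic range

# Background regimes by time of day (minutes from midnight):
# sleep 00:00-06:00 and 22:30-24:00, sedentary otherwise.
SLEEP_END_MIN = 6 * 60
SLEEP_START_MIN = 22 * 60 + 30

SESSION_WINDOW_MIN = (6 * 60, 21 * 60)  # sessions placed 06:00-21:00


@dataclass(frozen=True)
class ActivityProfile:
    """Epoch-intensity model for one activity.

    ``epoch_mean``/``epoch_sd`` parameterise a zero-truncated normal over 5-s
    ENMO epoch values (mg); ``raw_frequency`` is the dominant oscillation used
    when synthesising raw 100-Hz signal for this activity.
    """

    name: str
    epoch_mean: float
    epoch_sd: float
    raw_frequency: float = 1.0

    def __post_init__(self) -> None:
        if self.epoch_mean < 0 or self.epoch_sd < 0:
            raise ValueError("profile mean and sd must be non-negative")


def default_profiles() -> Dict[str, ActivityProfile]:
    """Default activity profiles (mg).

    Running and walking anchors come from published wrist-worn reference
    values; the other activities are plausible calibrated assumptions, not
    ground truth, and can be overridden wholesale.
    """
    specs = {
        "running": (760.0, 200.0, 2.6),
        "walking": (170.0, 56.0, 1.9),
        "cycling": (450.0, 250.0, 1.4),
        "gym": (300.0, 180.0, 1.0),
        "circuits": (420.0, 200.0, 1.2),
        "field_racket": (600.0, 250.0, 2.0),
        "swim": (200.0, 100.0, 0.8),
        "sedentary": (30.0, 25.0, 0.3),
        "sleep": (10.0, 10.0, 0.1),
        "nonwear": (0.0, 0.0, 0.0),
    }
    return {name: ActivityProfile(name, *v) for name, v in specs.items()}


@dataclass(frozen=True)
class Session:
    """One scheduled training session within a day."""

    activity: str
    start_min: float  # minutes from midnight
    duration_min: float
    miles: Optional[float] = None  # running sessions only
    rpe: int = 5
    intensity: float = 1.0  # multiplier on the activity profile mean

    @property
    def end_min(self) -> float:
        return self.start_min + self.duration_min


@dataclass
class DaySpec:
    """Ground-truth schedule for one participant-day."""

    participant_id: str
    date: _dt.date
    category: str  # running | other_training | rest
    sessions: List[Session] = field(default_factory=list)
    nonwear_bouts: List[Tuple[float, float]] = field(default_factory=list)  # (start_min, duration_min)

    def __post_init__(self) -> None:
        if self.category not in ("running", "other_training", "rest"):
            raise ValueError(f"unknown day category: {self.category}")
        has_run = any(s.activity == "running" for s in self.sessions)
        if self.category == "running" and not has_run:
            raise ValueError("running day must contain a running session")
        if self.category == "rest" and self.sessions:
            raise ValueError("rest day must contain no sessions")
        for s in self.sessions:
            if s.duration_min <= 0:
                raise ValueError("session durations must be positive")
        spans = sorted((s.start_min, s.end_min) for s in self.sessions)
        for (_, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("sessions overlap")


@dataclass
class LogNoise:
    """Self-report error model for the training log."""

    omission_prob: float = 0.0
    miles_rel_sd: float = 0.0
    rpe_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.omission_prob, self.miles_rel_sd, self.rpe_jitter_sd) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.omission_prob > 1:
            raise ValueError("omission probability must be <= 1")


@dataclass
class CohortConfig:
    """Configuration for :func:`generate_cohort`.

    Category probabilities are ordered (running, rest, other_training); the
    defaults mirror a roughly 46/43/11 split over ~1,500 monitored days.
    """

    n_participants: int = 35
    days_per_participant: int = 43
    category_probabilities: Tuple[float, float, float] = (0.46, 0.43, 0.11)
    other_activity_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "cycling": 0.30,
            "gym": 0.28,
            "circuits": 0.14,
            "field_racket": 0.12,
            "swim": 0.10,
            "walking": 0.06,
        }
    )
    log_noise: LogNoise = field(default_factory=LogNoise)
    pace_range_min_per_mile: Tuple[float, float] = (9.0, 11.0)
    run_duration_range_min: Tuple[float, float] = (30.0, 100.0)
    other_duration_range_min: Tuple[float, float] = (40.0, 80.0)
    second_run_prob: float = 0.08
    extra_other_on_run_day_prob: float = 0.10
    short_nonwear_prob: float = 0.10
    long_nonwear_prob: float = 0.025
    start_date: _dt.date = _dt.date(2016, 1, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.days_per_participant <= 0:
            raise ValueError("participant and day counts must be positive")
        if abs(sum(self.category_probabilities) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")
        if any(p < 0 for p in self.category_probabilities):
            raise ValueError("category probabilities must be non-negative")
        if self.other_activity_mix:
            if abs(sum(self.other_activity_mix.values()) - 1.0) > 1e-9:
                raise ValueError("other-activity mix must sum to 1")
            if any(p < 0 for p in self.other_activity_mix.values()):
                raise ValueError("other-activity mix must be non-negative")


@dataclass
class Cohort:
    """Output bundle of :func:`generate_cohort`."""

    day_specs: List[DaySpec]
    epoch_series: List[EpochSeries]
    log_entries: List[TrainingLogEntry]
    labels: List[DayLabel]


# ---------------------------------------------------------------------------
# epoch-level generation


def generate_day_epochs(
    spec: DaySpec,
    profiles: Optional[Dict[str, ActivityProfile]] = None,
    rng: Optional[np.random.Generator] = None,
) -> EpochSeries:
    """Simulate the full-day 17,280-epoch ENMO series for one day spec.

    Background epochs follow the sleep profile overnight and the sedentary
    profile during waking hours; session epochs are drawn from the session
    activity's profile (mean scaled by the session intensity multiplier) and
    truncated at zero; non-wear bouts are zeroed and flagged in the wear mask.
    """
    profiles = profiles if profiles is not None else default_profiles()
    rng = rng if rng is not None else np.random.default_rng()

    mean = np.empty(EPOCHS_PER_DAY)
    sd = np.empty(EPOCHS_PER_DAY)
    sleep, sedentary = profiles["sleep"], profiles["sedentary"]
    sleep_end = int(SLEEP_END_MIN * EPOCHS_PER_MIN)
    sleep_start = int(SLEEP_START_MIN * EPOCHS_PER_MIN)
    mean[:] = sedentary.epoch_mean
    sd[:] = sedentary.epoch_sd
    mean[:sleep_end] = sleep.epoch_mean
    sd[:sleep_end] = sleep.epoch_sd
    mean[sleep_start:] = sleep.epoch_mean
    sd[sleep_start:] = sleep.epoch_sd

    for s in spec.sessions:
        if s.activity not in profiles:
            raise KeyError(f"no profile for activity {s.activity!r}")
        prof = profiles[s.activity]
        i0 = int(round(s.start_min * EPOCHS_PER_MIN))
        i1 = i0 + int(round(s.duration_min * EPOCHS_PER_MIN))
        mean[i0:i1] = prof.epoch_mean * s.intensity
        sd[i0:i1] = prof.epoch_sd

    values = np.clip(rng.normal(mean, sd), 0.0, None)
    wear = np.ones(EPOCHS_PER_DAY, dtype=bool)
    for start_min, dur_min in spec.nonwear_bouts:
        i0 = int(round(start_min * EPOCHS_PER_MIN))
        i1 = i0 + int(round(dur_min * EPOCHS_PER_MIN))
        wear[i0:i1] = False
        values[i0:i1] = 0.0
    return EpochSeries(spec.participant_id, spec.date, values, wear)


# ---------------------------------------------------------------------------
# raw-signal generation


def generate_raw_segment(
    profile: ActivityProfile,
    duration_s: float,
    fs: float = 100.0,
    rng: Optional[np.random.Generator] = None,
    orientation: Sequence[float] = (0.0, 0.0, 1.0),
) -> RawSegment:
    """Synthesise a raw triaxial segment whose per-epoch ENMO matches ``profile``.

    The dynamic component is a rectified cosine along the gravity axis whose
    per-epoch amplitude is drawn from the profile's truncated normal, so an
    independent per-sample ENMO computation recovers the profile mean. A
    stationary (0, 0) profile yields pure gravity with vector magnitude
    1000 mg.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    g = np.asarray(orientation, dtype=float)
    g = g / np.linalg.norm(g)

    n_epochs = int(np.ceil(n / (EPOCH_S * fs)))
    epoch_targets = np.clip(rng.normal(profile.epoch_mean, profile.epoch_sd, n_epochs), 0.0, None)
    per_sample_target = np.repeat(epoch_targets, int(EPOCH_S * fs))[:n]

    if profile.epoch_mean == 0 and profile.epoch_sd == 0:
        dynamic = np.zeros(n)
    else:
        # integer cycles per 5-s epoch keep the epoch-mean of (1 - cos) at 1
        f_eff = max(1, round(profile.raw_frequency * EPOCH_S)) / EPOCH_S
        dynamic = per_sample_target * (1.0 - np.cos(2 * np.pi * f_eff * t))

    xyz = GRAVITY_MG * g[None, :] + dynamic[:, None] * g[None, :]
    xyz = np.clip(xyz, -MAX_ABS_MG, MAX_ABS_MG)
    return RawSegment(t, xyz[:, 0], xyz[:, 1], xyz[:, 2], fs=fs)


def generate_stationary_segment(
    orientations: Sequence[Sequence[float]],
    duration_each_s: float = 30.0,
    fs: float = 20.0,
    rng: Optional[np.random.Generator] = None,
    noise_sd: float = 2.0,
    offset: Sequence[float] = (0.0, 0.0, 0.0),
    scale: Sequence[float] = (1.0, 1.0, 1.0),
) -> RawSegment:
    """Concatenate stationary gravity-only bouts in the given orientations.

    ``offset``/``scale`` distort the signal so that applying the calibration
    ``raw * scale + offset`` recovers a unit-gravity magnitude — the parameter
    recovery target for the autocalibration routine.
    """
    rng = rng if rng is not None else np.random.default_rng()
    offset = np.asarray(offset, dtype=float)
    scale = np.asarray(scale, dtype=float)
    n_each = int(round(duration_each_s * fs))
    chunks = []
    for o in orientations:
        g = np.asarray(o, dtype=float)
        g = g / np.linalg.norm(g)
        true = GRAVITY_MG * g[None, :] + rng.normal(0.0, noise_sd, (n_each, 3))
        chunks.append((true - offset) / scale)
    xyz = np.vstack(chunks)
    t = np.arange(len(xyz)) / fs
    return RawSegment(t, xyz[:, 0], xyz[:, 1], xyz[:, 2], fs=fs)


# ---------------------------------------------------------------------------
# schedules, logs, labels


def _place_sessions(durations: Sequence[float], rng: np.random.Generator) -> List[float]:
    """Draw non-overlapping start minutes in the 06:00-21:00 window."""
    lo, hi = SESSION_WINDOW_MIN
    for _ in range(200):
        starts = [rng.uniform(lo, hi - d) for d in durations]
        spans = sorted(zip(starts, durations))
        if all(s0 + d0 <= s1 for (s0, d0), (s1, _) in zip(spans, spans[1:])):
            return starts
    # fall back to deterministic sequential placement
    starts, cursor = [], float(lo)
    for d in durations:
        starts.append(cursor)
        cursor += d + 10
    return starts


def _running_rpe(duration_min: float, intensity: float, rng: np.random.Generator) -> int:
    raw = 1.0 + 7.0 * (duration_min / 100.0) * intensity + rng.normal(0.0, 0.7)
    return int(np.clip(round(raw), 1, 10))


def _generate_day_spec(
    participant_id: str,
    date: _dt.date,
    category: str,
    pace_min_per_mile: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> DaySpec:
    sessions: List[Session] = []
    if category == "running":
        n_runs = 1 + int(rng.random() < config.second_run_prob)
        durations = [rng.uniform(*config.run_duration_range_min) for _ in range(n_runs)]
        extra_other = rng.random() < config.extra_other_on_run_day_prob and config.other_activity_mix
        if extra_other:
            durations.append(rng.uniform(*config.other_duration_range_min))
        starts = _place_sessions(durations, rng)
        for i in range(n_runs):
            intensity = float(np.clip(rng.normal(1.0, 0.10), 0.8, 1.3))
            miles = round(durations[i] / pace_min_per_mile, 2)
            rpe = _running_rpe(durations[i], intensity, rng)
            sessions.append(Session("running", starts[i], durations[i], miles, rpe, intensity))
        if extra_other:
            act = _draw_activity(config.other_activity_mix, rng)
            sessions.append(_other_session(act, starts[-1], durations[-1], rng))
    elif category == "other_training":
        duration = rng.uniform(*config.other_duration_range_min)
        start = _place_sessions([duration], rng)[0]
        act = _draw_activity(config.other_activity_mix, rng)
        sessions.append(_other_session(act, start, duration, rng))

    nonwear: List[Tuple[float, float]] = []
    if rng.random() < config.long_nonwear_prob:
        # long enough to fail the 10-h valid-day rule
        dur = rng.uniform(870.0, 1230.0)
        nonwear.append((rng.uniform(0.0, 1440.0 - dur), dur))
    elif rng.random() < config.short_nonwear_prob:
        # short bout placed overnight, clear of the session window
        dur = rng.uniform(30.0, 120.0)
        nonwear.append((rng.uniform(0.0, SLEEP_END_MIN - dur), dur))
    return DaySpec(participant_id, date, category, sessions, nonwear)


def _draw_activity(mix: Dict[str, float], rng: np.random.Generator) -> str:
    names = sorted(mix)
    probs = np.array([mix[n] for n in names])
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


def _other_session(activity: str, start: float, duration: float, rng: np.random.Generator) -> Session:
    intensity = float(np.clip(rng.normal(1.0, 0.10), 0.8, 1.3))
    rpe = int(np.clip(round(1.0 + 5.0 * duration / 100.0 + rng.normal(0.0, 1.0)), 1, 10))
    return Session(activity, start, duration, None, rpe, intensity)


def _minutes_to_time(minutes: float) -> _dt.time:
    total = int(round(minutes * 60))
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return _dt.time(min(h, 23), m, s)


def log_entries_for_spec(spec: DaySpec) -> List[TrainingLogEntry]:
    """Exact (noise-free) training-log entries for a day spec."""
    entries = []
    for s in spec.sessions:
        entries.append(
            TrainingLogEntry(
                participant_id=spec.participant_id,
                date=spec.date,
                start_time=_minutes_to_time(s.start_min),
                end_time=_minutes_to_time(s.end_min),
                activity=s.activity,
                miles=s.miles,
                rpe=s.rpe,
            )
        )
    return entries


def true_label_for_spec(spec: DaySpec) -> DayLabel:
    """Ground-truth day label implied by a day spec's sessions."""
    runs = [s for s in spec.sessions if s.activity == "running"]
    others = tuple(sorted({s.activity for s in spec.sessions if s.activity != "running"}))
    if runs:
        duration = sum(s.duration_min for s in runs)
        miles = sum(s.miles or 0.0 for s in runs)
        mean_rpe = float(np.mean([s.rpe for s in runs]))
        return DayLabel(
            spec.participant_id,
            spec.date,
            "running",
            others,
            miles,
            duration,
            mean_rpe,
            mean_rpe * duration,
        )
    if spec.sessions:
        duration = sum(s.duration_min for s in spec.sessions)
        return DayLabel(spec.participant_id, spec.date, "other_training", others, 0.0, duration)
    return DayLabel(spec.participant_id, spec.date, "rest")


def corrupt_training_log(
    entries: Sequence[TrainingLogEntry],
    log_noise: LogNoise,
    rng: Optional[np.random.Generator] = None,
) -> List[TrainingLogEntry]:
    """Apply the self-report error model to a list of log entries.

    Each entry is independently omitted with the configured probability;
    reported miles are multiplied by ``1 + N(0, miles_rel_sd)`` and floored at
    zero; RPE is jittered by ``N(0, rpe_jitter_sd)`` rounded and clamped to
    [1, 10].
    """
    rng = rng if rng is not None else np.random.default_rng()
    out: List[TrainingLogEntry] = []
    for e in entries:
        if rng.random() < log_noise.omission_prob:
            continue
        miles = e.miles
        if miles is not None and log_noise.miles_rel_sd > 0:
            miles = max(0.0, miles * (1.0 + rng.normal(0.0, log_noise.miles_rel_sd)))
        rpe = e.rpe
        if log_noise.rpe_jitter_sd > 0:
            rpe = int(np.clip(round(e.rpe + rng.normal(0.0, log_noise.rpe_jitter_sd)), 1, 10))
        out.append(replace(e, miles=miles, rpe=rpe))
    return out


def generate_cohort(
    config: CohortConfig,
    profiles: Optional[Dict[str, ActivityProfile]] = None,
) -> Cohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``."""
    profiles = profiles if profiles is not None else default_profiles()
    rng = np.random.default_rng(config.seed)
    categories = ("running", "rest", "other_training")
    probs = np.asarray(config.category_probabilities, dtype=float)

    day_specs: List[DaySpec] = []
    series: List[EpochSeries] = []
    clean_entries: List[TrainingLogEntry] = []
    labels: List[DayLabel] = []

    for p in range(config.n_participants):
        pid = f"P{p + 1:03d}"
        pace = rng.uniform(*config.pace_range_min_per_mile)
        for d in range(config.days_per_participant):
            date = config.start_date + _dt.timedelta(days=d)
            category = categories[int(rng.choice(3, p=probs))]
            spec = _generate_day_spec(pid, date, category, pace, config, rng)
            day_specs.append(spec)
            series.append(generate_day_epochs(spec, profiles, rng))
            clean_entries.extend(log_entries_for_spec(spec))
            labels.append(true_label_for_spec(spec))

    entries = corrupt_training_log(clean_entries, config.log_noise, rng)
    return Cohort(day_specs, series, entries, labels)


def designed_r2_dataset(
    n: int,
    r2: float,
    slope: float = 0.08,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Predictor/criterion pair with a designed population R-squared.

    ``x`` mimics daily minutes above 400 mg; ``y = slope * x + e`` with the
    noise variance chosen analytically from the realised variance of the
    signal so that the linear fit's expected variance explained equals ``r2``.
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    x = rng.uniform(28.0, 96.0, n)
    signal = slope * x
    noise_sd = float(np.std(signal)) * np.sqrt((1.0 - r2) / r2)
    y = signal + rng.normal(0.0, noise_sd, n)
    return x, y
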