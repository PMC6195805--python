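"""Training-log parsing, day labelling, and date-matching.

Day classification rule: any running session (all surface types) makes the
day a running day; otherwise any session makes it an other-training day;
days with no logged sessions are rest days. Multi-run days sum miles and
duration, average RPE over the running sessions, and recompute training
load as mean RPE x summed duration.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import DayLabel, TrainingLogEntry

#: Activity labels that count as running (all surface types).
RUNNING_ACTIVITIES = {
    "running",
    "run",
    "road_run",
    "off_road_run",
    "track_run",
    "treadmill_run",
}

LOG_COLUMNS = ["participant_id", "date", "start_time", "end_time", "activity", "miles", "rpe"]


def is_running_activity(activity: str) -> bool:
    return activity.strip().lower() in RUNNING_ACTIVITIES


@dataclass
class LogReadResult:
    entries: List[TrainingLogEntry]
    errors: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_time(text: str) -> _dt.time:
    for fmt in ("%H:%M:%S", "%H:%M"):
        try:
            return _dt.datetime.strptime(text.strip(), fmt).time()
        except ValueError:
            continue
    raise ValueError(f"unparseable time {text!r}")


def read_training_log(path) -> LogReadResult:
    """Read a training-log CSV, collecting row-level validation errors.

    Malformed rows (bad date/time, RPE outside 1-10, end before start) are
    reported by row number and excluded from the entry list; they are never
    silently dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"training log missing columns: {missing}")
    entries: List[TrainingLogEntry] = []
    errors: List[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            date = _dt.date.fromisoformat(str(row.date).strip())
            start = _parse_time(str(row.start_time))
            end = _parse_time(str(row.end_time))
            rpe = int(str(row.rpe).strip())
            if not 1 <= rpe <= 10:
                raise ValueError(f"rpe {rpe} outside 1-10")
            miles_txt = str(row.miles).strip()
            miles = float(miles_txt) if miles_txt else None
            if miles is not None and miles < 0:
                raise ValueError("miles must be non-negative")
            entry = TrainingLogEntry(
                participant_id=str(row.participant_id).strip(),
                date=date,
                start_time=start,
                end_time=end,
                activity=str(row.activity).strip(),
                miles=miles,
                rpe=rpe,
            )
            if entry.duration_min <= 0:
                raise ValueError("end time must be after start time (overnight sessions rejected)")
            entries.append(entry)
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    return LogReadResult(entries, errors)


def write_training_log(entries: Sequence[TrainingLogEntry], path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "participant_id": e.participant_id,
                "date": e.date.isoformat(),
                "start_time": e.start_time.strftime("%H:%M:%S"),
                "end_time": e.end_time.strftime("%H:%M:%S"),
                "activity": e.activity,
                "miles": "" if e.miles is None else repr(float(e.miles)),
                "rpe": e.rpe,
            }
        )
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False)


def label_days(
    entries: Iterable[TrainingLogEntry],
    calendar: Optional[Iterable[Tuple[str, _dt.date]]] = None,
) -> List[DayLabel]:
    """Classify every participant-day as running / other_training / rest.

    ``calendar`` lists all monitored (participant, date) pairs; monitored
    days with no log entries become rest days. Without a calendar, only days
    present in the log are labelled.
    """
    by_day: Dict[Tuple[str, _dt.date], List[TrainingLogEntry]] = {}
    for e in entries:
        by_day.setdefault((e.participant_id, e.date), []).append(e)

    keys = set(by_day)
    if calendar is not None:
        keys |= {(pid, date) for pid, date in calendar}

    labels: List[DayLabel] = []
    for pid, date in sorted(keys):
        day_entries = by_day.get((pid, date), [])
        runs = [e for e in day_entries if is_running_activity(e.activity)]
        others = tuple(sorted({e.activity for e in day_entries if not is_running_activity(e.activity)}))
        if runs:
            duration = sum(e.duration_min for e in runs)
            miles = sum(e.miles or 0.0 for e in runs)
            mean_rpe = float(np.mean([e.rpe for e in runs]))
            labels.append(
                DayLabel(pid, date, "running", others, miles, duration, mean_rpe, mean_rpe * duration)
            )
        elif day_entries:
            duration = sum(e.duration_min for e in day_entries)
            labels.append(DayLabel(pid, date, "other_training", others, 0.0, duration))
        else:
            labels.append(DayLabel(pid, date, "rest"))
    return labels


def labels_frame(labels: Sequence[DayLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [l.participant_id for l in labels],
            "date": [l.date for l in labels],
            "category": [l.category for l in labels],
            "other_activities": ["|".join(l.other_activities) for l in labels],
            "miles": [l.miles for l in labels],
            "duration": [l.duration for l in labels],
            "mean_rpe": [l.mean_rpe for l in labels],
            "training_load": [l.training_load for l in labels],
        }
    )


def match_days(
    labels: pd.DataFrame, metrics: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Inner-join day labels with accelerometer metrics on participant-day.

    Returns (matched, unmatched accelerometer days, unmatched label days).
    Unmatched accelerometer days are candidate unlogged activity and are
    reported, not discarded silently. Duplicate participant-days on either
    side are an error.
    """
    key = ["participant_id", "date"]
    for name, df in (("labels", labels), ("metrics", metrics)):
        dup = df.duplicated(subset=key)
        if dup.any():
            raise ValueError(f"duplicate participant-day rows in {name}")
    matched = metrics.merge(labels, on=key, how="inner")
    unmatched_metrics = metrics.merge(labels[key], on=key, how="left", indicator=True)
    unmatched_metrics = unmatched_metrics[unmatched_metrics["_merge"] == "left_only"].drop(columns="_merge")
    unmatched_labels = labels.merge(metrics[key], on=key, how="left", indicator=True)
    unmatched_labels = unmatched_labels[unmatched_labels["_merge"] == "left_only"].drop(columns="_merge")
    return matched, unmatched_metrics, unmatched_labels
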