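"""CSV/JSON readers and writers for the documented file formats."""

from __future__ import annotations

import datetime as _dt
import json
from typing import List, Sequence

import numpy as np
import pandas as pd

from .types import CalibrationParams, DayMetrics, EpochSeries, RawSegment
from .metrics import BIN_EDGES


def write_epoch_csv(series: Sequence[EpochSeries], path) -> None:
    """Epoch CSV: participant_id, date, epoch_index, enmo_mg, wear."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "date": s.date.isoformat() if s.date else "",
                    "epoch_index": np.arange(len(s)),
                    "enmo_mg": s.values,
                    "wear": s.wear.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epoch_csv(path) -> List[EpochSeries]:
    df = pd.read_csv(path)
    out = []
    for (pid, date), grp in df.groupby(["participant_id", "date"], sort=True):
        grp = grp.sort_values("epoch_index")
        out.append(
            EpochSeries(
                str(pid),
                _dt.date.fromisoformat(str(date)),
                grp["enmo_mg"].to_numpy(dtype=float),
                grp["wear"].to_numpy(dtype=bool),
            )
        )
    return out


def write_raw_csv(raw: RawSegment, path, start: _dt.datetime = _dt.datetime(2016, 1, 4)) -> None:
    """Raw CSV: timestamp (ISO-8601 with fractional seconds), x_mg, y_mg, z_mg."""
    ts = [(start + _dt.timedelta(seconds=t)).isoformat(timespec="milliseconds") for t in raw.timestamps]
    pd.DataFrame({"timestamp": ts, "x_mg": raw.x, "y_mg": raw.y, "z_mg": raw.z}).to_csv(path, index=False)


def read_raw_csv(path) -> RawSegment:
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"])
    seconds = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    dt = np.median(np.diff(seconds)) if len(seconds) > 1 else 0.01
    return RawSegment(
        seconds,
        df["x_mg"].to_numpy(dtype=float),
        df["y_mg"].to_numpy(dtype=float),
        df["z_mg"].to_numpy(dtype=float),
        fs=1.0 / dt if dt > 0 else 100.0,
    )


def write_metrics_csv(metrics: Sequence[DayMetrics], path, include_bins: bool = True) -> None:
    rows = []
    for m in metrics:
        row = {
            "participant_id": m.participant_id,
            "date": m.date.isoformat(),
            "wear_h": m.wear_h,
            "avg_accel": m.avg_accel,
            "most_active_30": m.most_active_30,
            "mins_ge_400": m.mins_ge_400,
            "wl_400_4000": m.wl_400_4000,
        }
        if include_bins:
            for edge, minutes in zip(BIN_EDGES[:-1], m.bin_minutes[:-1]):
                row[f"bin_{int(edge)}"] = minutes
            row["bin_4000_plus"] = m.bin_minutes[-1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = df["date"].astype(str)
    return df


def write_calibration_json(params: CalibrationParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "offset_mg": list(params.offset),
                "scale": list(params.scale),
                "error_before_mg": params.error_before,
                "error_after_mg": params.error_after,
                "calibrated": params.calibrated,
                "message": params.message,
            },
            fh,
            indent=2,
        )
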