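"""End-to-end study orchestration: simulate -> filter -> metrics -> label ->
classify -> validate -> report.

Every stage persists its intermediate CSV so report numbers can be
recomputed from disk; the report JSON carries the config hash and seed for
provenance. All paper-gap choices (cutpoint rule, CV unit, workload bin
representative, waking window) are config keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    CutpointResult,
    accuracy_breakdown,
    classify_days,
    fit_cutpoint,
    loocv_classification,
)
from .io import write_metrics_csv
from .metrics import day_metrics, metrics_frame
from .processing import filter_valid_days
from .synthetic import Cohort, CohortConfig, LogNoise, generate_cohort
from .training_log import label_days, labels_frame, match_days
from .validity import validity_frame, validity_matrix

log = logging.getLogger("wristload")

CLASSIFIER_METRICS = ("avg_accel", "most_active_30", "mins_ge_400")
VALIDITY_CLASSIFIERS = ("mins_ge_400", "most_active_30")


@dataclass
class StudyConfig:
    """Configuration for :func:`run_study`; loadable from YAML."""

    output_dir: str = "study_out"
    seed: int = 7
    # cohort
    n_participants: int = 35
    days_per_participant: int = 43
    category_probabilities: Tuple[float, float, float] = (0.46, 0.43, 0.11)
    log_noise: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    # processing
    min_wear_h: float = 10.0
    waking_window: Optional[Tuple[float, float]] = None
    # metrics
    workload_representative: str = "midpoint"
    # classification / regression
    cutpoint_rule: str = "youden"
    cv_unit: str = "participant"
    write_epochs: bool = False

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("category_probabilities", "log_noise", "waking_window"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_participants=self.n_participants,
            days_per_participant=self.days_per_participant,
            category_probabilities=self.category_probabilities,
            log_noise=LogNoise(*self.log_noise),
            seed=self.seed,
        )

    def hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cutpoint_row(result: CutpointResult, cv) -> Dict:
    return {
        "metric": result.metric_name,
        "cutpoint": result.cutpoint,
        "auc": result.auc,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "pct_running_correct": result.pct_running_correct,
        "pct_nonrunning_correct": result.pct_nonrunning_correct,
        "pct_rest_correct": result.pct_rest_correct,
        "pct_other_training_correct": result.pct_other_training_correct,
        "cv_mean_auc": cv.mean_auc,
        "cv_min_auc": cv.min_auc,
        "cv_pooled_accuracy": cv.pooled_accuracy,
    }


def run_study(config: StudyConfig) -> Dict:
    """Run the full pipeline on a synthetic cohort; return the report dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate
    log.info("simulate: %d participants x %d days", config.n_participants, config.days_per_participant)
    cohort = generate_cohort(config.cohort_config())
    n_days_raw = len(cohort.epoch_series)

    # --- wear filter
    valid, retention = filter_valid_days(
        cohort.epoch_series, min_wear_h=config.min_wear_h, waking_window=config.waking_window
    )
    log.info("wear filter: %d/%d days retained (%.3f)", len(valid), n_days_raw, retention)

    # --- metrics
    metrics = [day_metrics(s, workload_representative=config.workload_representative) for s in valid]
    mdf = metrics_frame(metrics)
    write_metrics_csv(metrics, outdir / "day_metrics.csv")
    if config.write_epochs:
        from .io import write_epoch_csv

        write_epoch_csv(valid, outdir / "epochs.csv")

    # --- label + match
    calendar = [(s.participant_id, s.date) for s in cohort.epoch_series]
    labels = label_days(cohort.log_entries, calendar)
    ldf = labels_frame(labels)
    ldf.to_csv(outdir / "day_labels.csv", index=False)
    matched, unmatched_m, unmatched_l = match_days(ldf, mdf)
    unmatched_m.to_csv(outdir / "unmatched_accelerometer_days.csv", index=False)
    log.info("matched %d days (%d accel-only, %d log-only)", len(matched), len(unmatched_m), len(unmatched_l))
    category_counts = matched["category"].value_counts().to_dict()

    # --- classify
    if matched["category"].nunique() < 2 or "running" not in set(matched["category"]):
        raise ValueError(
            "classification stage: matched days contain a single class "
            f"(categories: {sorted(set(matched['category']))}); cannot fit ROC"
        )
    cutpoint_table: List[Dict] = []
    misclassification: Dict[str, Dict] = {}
    predictions = matched[["participant_id", "date", "category"]].copy()
    cutpoints: Dict[str, float] = {}
    for metric in CLASSIFIER_METRICS:
        roc, choice = fit_cutpoint(matched, metric, rule=config.cutpoint_rule)
        pred = classify_days(matched[metric].to_numpy(), choice.cutpoint)
        breakdown = accuracy_breakdown(pred, matched, metric, choice.cutpoint, roc.auc)
        group_col = "participant_id" if config.cv_unit == "participant" else None
        if group_col is None:
            matched = matched.reset_index(drop=True)
            matched["_day_id"] = matched.index.astype(str)
            group_col = "_day_id"
        cv = loocv_classification(matched, metric, group_col=group_col, rule=config.cutpoint_rule)
        cutpoint_table.append(_cutpoint_row(breakdown, cv))
        misclassification[metric] = {
            "misclassified_pct": breakdown.activity_misclassification,
            "occurrences": breakdown.activity_occurrences,
        }
        predictions[f"pred_{metric}"] = pred.astype(int)
        cutpoints[metric] = choice.cutpoint
    predictions.to_csv(outdir / "day_predictions.csv", index=False)

    # --- validity
    vresults = validity_matrix(
        matched, {m: cutpoints[m] for m in VALIDITY_CLASSIFIERS if m in cutpoints}
    )
    vdf = validity_frame(vresults)
    vdf.to_csv(outdir / "validity_matrix.csv", index=False)

    report = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
            "cutpoint_rule": config.cutpoint_rule,
            "cv_unit": config.cv_unit,
        },
        "cohort": {
            "n_participants": config.n_participants,
            "days_generated": n_days_raw,
            "days_valid": len(valid),
            "wear_retention": retention,
            "days_matched": len(matched),
            "category_counts": category_counts,
        },
        "cutpoints": cutpoint_table,
        "misclassification": misclassification,
        "validity": vdf.to_dict(orient="records"),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    _write_text_report(report, outdir / "report.txt")
    return report


def _write_text_report(report: Dict, path: Path) -> None:
    lines = ["Study report", "============", ""]
    c = report["cohort"]
    lines.append(
        f"Cohort: {c['n_participants']} participants, {c['days_valid']}/{c['days_generated']} "
        f"valid days (retention {c['wear_retention']:.3f}), {c['days_matched']} matched"
    )
    lines.append(f"Category counts: {c['category_counts']}")
    lines.append("")
    lines.append("Cutpoints (running vs nonrunning days)")
    for row in report["cutpoints"]:
        lines.append(
            f"  {row['metric']:>15}: cutpoint {row['cutpoint']:.1f}, AUC {row['auc']:.3f}, "
            f"sens {row['sensitivity']:.3f}, spec {row['specificity']:.3f}, "
            f"CV mean AUC {row['cv_mean_auc']:.3f}"
        )
    lines.append("")
    lines.append("Other-training misclassified as running (%)")
    for metric, d in report["misclassification"].items():
        parts = [f"{a} {p:.0f}%" for a, p in d["misclassified_pct"].items()]
        lines.append(f"  {metric:>15}: " + ", ".join(parts))
    lines.append("")
    lines.append("Validity matrix (R^2 / LOOCV R^2)")
    for row in report["validity"]:
        lines.append(
            f"  classifier={row['classifier_metric']:>14} {row['predictor']:>12} -> "
            f"{row['criterion']:<13} n={row['n']:>4}  r2={row['r2']:.3f}  cv={row['loocv_r2']:.3f}"
        )
    path.write_text("\n".join(lines) + "\n")
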