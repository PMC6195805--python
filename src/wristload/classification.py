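"""ROC cutpoint analysis for running vs nonrunning day discrimination.

Empirical ROC curves over observed metric values (a day is classified as
running when its metric is at or above the threshold), optimal cutpoints
balancing sensitivity and specificity (Youden's J with a |sens - spec|
tie-break), accuracy breakdowns with per-activity misclassification,
leave-one-participant-out cross-validation, and the Hanley-McNeil AUROC
sample-size computation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

CUTPOINT_RULES = ("youden", "closest-topleft")


@dataclass
class ROCCurve:
    """Empirical ROC over all distinct observed values as thresholds.

    ``thresholds`` ascend and end with +inf (classify nothing as running);
    sensitivity is non-increasing and specificity non-decreasing along it.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class CutpointChoice:
    cutpoint: float
    threshold_value: float  # observed value achieving the optimum
    sensitivity: float
    specificity: float
    youden_j: float
    uninformative: bool = False


@dataclass
class CutpointResult:
    """Cutpoint plus full accuracy breakdown for one metric."""

    metric_name: str
    cutpoint: float
    auc: float
    sensitivity: float
    specificity: float
    pct_running_correct: float
    pct_nonrunning_correct: float
    pct_rest_correct: float
    pct_other_training_correct: float
    activity_misclassification: Dict[str, float] = field(default_factory=dict)
    activity_occurrences: Dict[str, int] = field(default_factory=dict)
    n_days: int = 0


@dataclass
class CVFold:
    fold_id: str
    n_days: int
    cutpoint: float
    accuracy: float
    auc: float = float("nan")  # NaN when the held-out fold is single-class
    single_class: bool = False


@dataclass
class CVResult:
    metric_name: str
    folds: List[CVFold]
    mean_auc: float
    min_auc: float
    pooled_accuracy: float


def roc_curve(values: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """Empirical ROC curve; AUC equals the Mann-Whitney statistic (ties 0.5)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    thresholds = np.append(np.unique(values), np.inf)
    # counts at/above each threshold via cumulative sums over sorted values
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    pos_sorted = np.sort(values[labels])
    neg_sorted = np.sort(values[~labels])
    for i, t in enumerate(thresholds):
        tp = n_pos - np.searchsorted(pos_sorted, t, side="left")
        fp = n_neg - np.searchsorted(neg_sorted, t, side="left")
        sens[i] = tp / n_pos
        spec[i] = (n_neg - fp) / n_neg

    ranks = stats.rankdata(values)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return ROCCurve(thresholds, sens, spec, float(auc), n_pos, n_neg)


def optimal_cutpoint(roc: ROCCurve, rule: str = "youden") -> CutpointChoice:
    """Select the threshold balancing sensitivity and specificity.

    ``youden`` maximises J = sens + spec - 1, breaking ties by minimal
    |sens - spec|; ``closest-topleft`` minimises the Euclidean distance to the
    (sens=1, spec=1) corner. The reported cutpoint is the midpoint between
    the optimal observed value and the next lower observed value, so it falls
    strictly between the two classes wherever the data separate.
    """
    if rule not in CUTPOINT_RULES:
        raise ValueError(f"unknown cutpoint rule {rule!r}")
    j = roc.sensitivity + roc.specificity - 1.0
    if rule == "youden":
        best_score = j.max()
        candidates = np.flatnonzero(j == best_score)
        balance = np.abs(roc.sensitivity[candidates] - roc.specificity[candidates])
        candidates = candidates[balance == balance.min()]
        idx = int(candidates[0])
        uninformative = best_score <= 0
        if uninformative:
            warnings.warn("uninformative ROC: Youden J <= 0 at every threshold")
    else:
        d2 = (1 - roc.sensitivity) ** 2 + (1 - roc.specificity) ** 2
        idx = int(np.argmin(d2))
        uninformative = j[idx] <= 0

    t = roc.thresholds[idx]
    finite = roc.thresholds[np.isfinite(roc.thresholds)]
    if not np.isfinite(t):
        cutpoint = float(finite[-1]) + 1.0  # nothing classified running
    else:
        below = finite[finite < t]
        cutpoint = float((t + below[-1]) / 2.0) if below.size else float(t)
    return CutpointChoice(
        cutpoint=cutpoint,
        threshold_value=float(t),
        sensitivity=float(roc.sensitivity[idx]),
        specificity=float(roc.specificity[idx]),
        youden_j=float(j[idx]),
        uninformative=bool(uninformative),
    )


def classify_days(values: Sequence[float], cutpoint: float) -> np.ndarray:
    """Running iff metric value >= cutpoint (inclusive)."""
    if not np.isfinite(cutpoint):
        raise ValueError("cutpoint must be finite")
    return np.asarray(values, dtype=float) >= cutpoint


def accuracy_breakdown(
    predicted: Sequence[bool],
    labels: pd.DataFrame,
    metric_name: str = "",
    cutpoint: float = float("nan"),
    auc: float = float("nan"),
) -> CutpointResult:
    """Accuracy breakdown against a labels frame.

    ``labels`` needs columns ``category`` (running/other_training/rest) and
    ``other_activities`` (pipe-joined activity labels for the day's
    non-running sessions). Per-activity misclassification is the percentage
    of that activity's other-training occurrences on days predicted running;
    activities with zero occurrences are omitted.
    """
    predicted = np.asarray(predicted, dtype=bool)
    category = labels["category"].to_numpy()
    actual = category == "running"
    if len(predicted) != len(actual):
        raise ValueError("predictions and labels must align")

    tp = int(np.sum(predicted & actual))
    tn = int(np.sum(~predicted & ~actual))
    n_pos = int(actual.sum())
    n_neg = int((~actual).sum())
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")

    rest = category == "rest"
    other = category == "other_training"
    pct_rest = float(np.sum(~predicted & rest)) / rest.sum() * 100 if rest.any() else float("nan")
    pct_other = float(np.sum(~predicted & other)) / other.sum() * 100 if other.any() else float("nan")

    occurrences: Dict[str, int] = {}
    miscls: Dict[str, int] = {}
    acts = labels["other_activities"].fillna("").to_numpy()
    for pred, is_other, act_str in zip(predicted, other, acts):
        if not is_other or not act_str:
            continue
        for act in str(act_str).split("|"):
            occurrences[act] = occurrences.get(act, 0) + 1
            if pred:
                miscls[act] = miscls.get(act, 0) + 1
    misclassification = {
        act: miscls.get(act, 0) / n * 100.0 for act, n in sorted(occurrences.items())
    }

    return CutpointResult(
        metric_name=metric_name,
        cutpoint=cutpoint,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        pct_running_correct=sens * 100 if n_pos else float("nan"),
        pct_nonrunning_correct=spec * 100 if n_neg else float("nan"),
        pct_rest_correct=pct_rest,
        pct_other_training_correct=pct_other,
        activity_misclassification=misclassification,
        activity_occurrences=dict(sorted(occurrences.items())),
        n_days=len(predicted),
    )


def fit_cutpoint(
    df: pd.DataFrame, metric: str, rule: str = "youden"
) -> Tuple[ROCCurve, CutpointChoice]:
    """Fit the ROC and optimal cutpoint for one metric column of a matched frame."""
    labels = (df["category"] == "running").to_numpy()
    roc = roc_curve(df[metric].to_numpy(), labels)
    return roc, optimal_cutpoint(roc, rule=rule)


def loocv_classification(
    df: pd.DataFrame,
    metric: str,
    group_col: str = "participant_id",
    rule: str = "youden",
) -> CVResult:
    """Leave-one-group-out cross-validation of the cutpoint classifier.

    Default unit is the participant (respecting day clustering); pass the
    index as ``group_col`` for per-day folds. Held-out AUC is computed only
    when the held-out fold contains both classes; folds whose training data
    are single-class are skipped with a warning.
    """
    groups = df[group_col].unique()
    if len(groups) < 3:
        raise ValueError("leave-one-out CV needs at least 3 groups")
    folds: List[CVFold] = []
    correct = 0
    total = 0
    for g in groups:
        test = df[df[group_col] == g]
        train = df[df[group_col] != g]
        train_labels = train["category"] == "running"
        if train_labels.all() or not train_labels.any():
            warnings.warn(f"fold {g!r} skipped: single-class training data")
            continue
        roc = roc_curve(train[metric].to_numpy(), train_labels.to_numpy())
        choice = optimal_cutpoint(roc, rule=rule)
        pred = classify_days(test[metric].to_numpy(), choice.cutpoint)
        actual = (test["category"] == "running").to_numpy()
        acc = float(np.mean(pred == actual))
        correct += int(np.sum(pred == actual))
        total += len(test)
        single = actual.all() or not actual.any()
        auc = float("nan")
        if not single:
            auc = roc_curve(test[metric].to_numpy(), actual).auc
        folds.append(
            CVFold(str(g), len(test), choice.cutpoint, acc, auc, single_class=single)
        )
    aucs = np.array([f.auc for f in folds if not f.single_class])
    return CVResult(
        metric_name=metric,
        folds=folds,
        mean_auc=float(aucs.mean()) if aucs.size else float("nan"),
        min_auc=float(aucs.min()) if aucs.size else float("nan"),
        pooled_accuracy=correct / total if total else float("nan"),
    )


def auroc_sample_size(
    auc_alt: float,
    auc_null: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.80,
    ratio: float = 1.0,
) -> Tuple[int, int]:
    """Per-group and total days needed to distinguish two AUROCs.

    Hanley-McNeil negative-exponential approximation with equal-group
    variance kernel V(theta) = Q1 + Q2 - 2 theta^2, Q1 = theta/(2 - theta),
    Q2 = 2 theta^2 / (1 + theta); two-sided alpha. Returns
    (n positive days, total days) with ceiling rounding per group.
    """
    if not 0.5 <= auc_null < auc_alt < 1.0:
        raise ValueError("need 0.5 <= auc_null < auc_alt < 1")
    if ratio <= 0:
        raise ValueError("allocation ratio must be positive")

    def kernel(theta: float) -> float:
        q1 = theta / (2.0 - theta)
        q2 = 2.0 * theta**2 / (1.0 + theta)
        return q1 + q2 - 2.0 * theta**2

    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    num = (z_a * math.sqrt(kernel(auc_null)) + z_b * math.sqrt(kernel(auc_alt))) ** 2
    n_pos = math.ceil(num / (auc_alt - auc_null) ** 2)
    total = n_pos + math.ceil(n_pos * ratio)
    return n_pos, total
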