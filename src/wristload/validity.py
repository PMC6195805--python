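"""Convergent validity: variance in training-log criteria explained by
accelerometer training-load metrics on classified running days.

Ordinary least squares of each criterion (miles, duration, training load)
on each predictor (Mins>=400mg, WL400-4000mg), with leave-one-participant-
out cross-validated R-squared (pooled PRESS against the global mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

PREDICTORS = ("mins_ge_400", "wl_400_4000")
CRITERIA = ("miles", "duration", "training_load")
LOW_N = 10


@dataclass
class FitResult:
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass
class ValidityResult:
    """One cell of the validity matrix."""

    classifier_metric: str  # metric used to select running days ("log" for log-labelled)
    predictor: str
    criterion: str
    n: int
    slope: float
    intercept: float
    r2: float
    loocv_r2: float
    low_n: bool = False


def fit_validity(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS of criterion on predictor; R^2 = 1 - SS_res / SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must align")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return FitResult(float(res.slope), float(res.intercept), r2, len(x))


def loocv_r2(
    df: pd.DataFrame,
    predictor: str,
    criterion: str,
    group_col: str = "participant_id",
) -> float:
    """Leave-one-group-out predicted R-squared.

    For each group, fit on all other groups' days and predict the held-out
    days; pooled PRESS over all predicted days is compared against the
    global-mean total sum of squares. Can be negative when the model
    generalises worse than the mean; always <= 1. Folds whose training
    predictor has zero variance are skipped with a warning.
    """
    groups = df[group_col].unique()
    if len(groups) < 3:
        raise ValueError("leave-one-out CV needs at least 3 groups")
    y_all = df[criterion].to_numpy(dtype=float)
    press = 0.0
    n_predicted = 0
    for g in groups:
        test = df[df[group_col] == g]
        train = df[df[group_col] != g]
        x_tr = train[predictor].to_numpy(dtype=float)
        if np.ptp(x_tr) == 0:
            warnings.warn(f"fold {g!r} skipped: zero training predictor variance")
            continue
        fit = fit_validity(x_tr, train[criterion].to_numpy(dtype=float))
        pred = fit.intercept + fit.slope * test[predictor].to_numpy(dtype=float)
        press += float(np.sum((test[criterion].to_numpy(dtype=float) - pred) ** 2))
        n_predicted += len(test)
    if n_predicted == 0:
        return float("nan")
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    return 1.0 - press / ss_tot if ss_tot > 0 else float("nan")


def validity_matrix(
    matched: pd.DataFrame,
    cutpoints: Dict[str, float],
    predictors: Sequence[str] = PREDICTORS,
    criteria: Sequence[str] = CRITERIA,
    include_log_labelled: bool = True,
    group_col: str = "participant_id",
) -> List[ValidityResult]:
    """All classifier x predictor x criterion validity cells.

    For each classifier metric, days predicted running by its cutpoint are
    selected (misclassified nonrunning days legitimately enter with their
    logged criteria, e.g. zero miles); optionally the log-labelled running
    days are analysed as a secondary set under classifier name ``"log"``.
    Cells with fewer than 10 selected days are flagged low-n but still
    computed when at least 3 days remain.
    """
    selections: List[Tuple[str, pd.DataFrame]] = []
    for metric, cutpoint in cutpoints.items():
        selections.append((metric, matched[matched[metric] >= cutpoint]))
    if include_log_labelled:
        selections.append(("log", matched[matched["category"] == "running"]))

    results: List[ValidityResult] = []
    for name, sel in selections:
        for predictor in predictors:
            for criterion in criteria:
                n = len(sel)
                if n < 3:
                    warnings.warn(f"cell {name}/{predictor}/{criterion} skipped: n={n}")
                    continue
                fit = fit_validity(sel[predictor], sel[criterion])
                cv = float("nan")
                if sel[group_col].nunique() >= 3:
                    cv = loocv_r2(sel, predictor, criterion, group_col=group_col)
                results.append(
                    ValidityResult(
                        classifier_metric=name,
                        predictor=predictor,
                        criterion=criterion,
                        n=n,
                        slope=fit.slope,
                        intercept=fit.intercept,
                        r2=fit.r2,
                        loocv_r2=cv,
                        low_n=n < LOW_N,
                    )
                )
    return results


def validity_frame(results: Sequence[ValidityResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
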