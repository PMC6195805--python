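import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wristload.classification import (
    accuracy_breakdown,
    auroc_sample_size,
    classify_days,
    loocv_classification,
    optimal_cutpoint,
    roc_curve,
)


def brute_force_auc(values, labels):
    """Oracle: pairwise concordance with ties credited 0.5."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_cutpoint(values, labels):
    """Oracle: exhaustive scan over all candidate thresholds with the stated
    tie-breaks (max J, then min |sens - spec|, then lowest threshold)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    candidates = list(np.unique(values)) + [np.inf]
    best = None
    for t in candidates:
        pred = values >= t
        sens = np.sum(pred & labels) / labels.sum()
        spec = np.sum(~pred & ~labels) / (~labels).sum()
        key = (-(sens + spec - 1), abs(sens - spec), t)
        if best is None or key < best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


class TestROCCurve:
    def test_perfect_separation(self):
        roc = roc_curve([10, 12, 1, 2], [True, True, False, False])
        assert roc.auc == 1.0

    def test_no_information(self):
        roc = roc_curve([5, 5, 5, 5], [True, True, False, False])
        assert roc.auc == 0.5

    def test_hand_counted_pairs(self):
        # positives {5, 3}, negatives {4, 1}: 3 of 4 pairs concordant
        roc = roc_curve([5, 3, 4, 1], [True, True, False, False])
        assert roc.auc == 0.75

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1, 2], [True, True])

    def test_sensitivity_monotone_in_threshold(self, rng):
        values = rng.normal(0, 1, 200)
        labels = rng.random(200) < 0.5
        roc = roc_curve(values, labels)
        assert np.all(np.diff(roc.sensitivity) <= 0)
        assert np.all(np.diff(roc.specificity) >= 0)

    def test_auc_equals_brute_force_exactly(self, rng):
        for n in (10, 57, 200):
            values = np.round(rng.normal(0, 2, n), 1)  # rounding induces ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_curve(values, labels).auc == brute_force_auc(values, labels)


class TestOptimalCutpoint:
    def test_midpoint_between_classes(self):
        roc = roc_curve([10, 12, 1, 2], [True, True, False, False])
        choice = optimal_cutpoint(roc)
        assert choice.cutpoint == 6.0  # midpoint of 2 and 10
        assert choice.sensitivity == 1.0 and choice.specificity == 1.0

    def test_uninformative_data_warns(self):
        roc = roc_curve([1, 2, 1, 2], [True, True, False, False])
        with pytest.warns(UserWarning, match="uninformative"):
            choice = optimal_cutpoint(roc)
        assert choice.uninformative

    def test_exhaustive_enumeration_oracle(self, rng):
        values = [3.0, 5.0, 7.0, 2.0, 4.0]
        labels = [True, True, True, False, False]
        roc = roc_curve(values, labels)
        choice = optimal_cutpoint(roc)
        t, sens, spec = brute_force_cutpoint(values, labels)
        assert choice.threshold_value == t
        assert choice.sensitivity == sens and choice.specificity == spec

    def test_matches_exhaustive_search_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 60))
            values = np.round(rng.normal(0, 1, n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_curve(values, labels)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                choice = optimal_cutpoint(roc)
            t, sens, spec = brute_force_cutpoint(values, labels)
            assert choice.threshold_value == t
            assert (choice.sensitivity, choice.specificity) == (sens, spec)

    def test_closest_topleft_rule(self):
        roc = roc_curve([10, 12, 1, 2], [True, True, False, False])
        choice = optimal_cutpoint(roc, rule="closest-topleft")
        assert choice.cutpoint == 6.0
        with pytest.raises(ValueError):
            optimal_cutpoint(roc, rule="nonsense")


class TestClassifyDays:
    def test_boundary_inclusive(self):
        assert classify_days([5.0], 5.0)[0]

    def test_all_below(self):
        assert not classify_days([1, 2, 3], 10.0).any()

    def test_accuracy_identity_two_ways(self, rng):
        values = rng.normal(0, 1, 500)
        labels = rng.random(500) < 0.5
        pred = classify_days(values, 0.1)
        tp = np.sum(pred & labels)
        tn = np.sum(~pred & ~labels)
        assert (tp + tn) / 500 == np.mean(pred == labels)

    def test_nonfinite_cutpoint_rejected(self):
        with pytest.raises(ValueError):
            classify_days([1.0], float("inf"))


class TestAccuracyBreakdown:
    def _labels(self, categories, activities=None):
        return pd.DataFrame(
            {
                "category": categories,
                "other_activities": activities or ["" for _ in categories],
            }
        )

    def test_all_correct(self):
        labels = self._labels(["running", "rest", "other_training"], ["", "", "gym"])
        result = accuracy_breakdown([True, False, False], labels)
        assert result.pct_running_correct == 100.0
        assert result.pct_nonrunning_correct == 100.0
        assert result.activity_misclassification == {"gym": 0.0}

    def test_cycling_misclassification_counting(self):
        n = 47
        categories = ["other_training"] * n + ["running"]
        activities = ["cycling"] * n + [""]
        predicted = [True] * 15 + [False] * (n - 15) + [True]
        result = accuracy_breakdown(predicted, self._labels(categories, activities))
        assert result.activity_misclassification["cycling"] == pytest.approx(15 / 47 * 100)
        assert round(result.activity_misclassification["cycling"], 1) == 31.9
        assert result.activity_occurrences["cycling"] == 47

    def test_percentages_consistent_with_confusion_counts(self, rng):
        n = 300
        categories = rng.choice(["running", "rest", "other_training"], n)
        activities = ["gym" if c == "other_training" else "" for c in categories]
        predicted = rng.random(n) < 0.5
        labels = self._labels(list(categories), activities)
        result = accuracy_breakdown(predicted, labels)
        actual = categories == "running"
        sens = np.sum(predicted & actual) / actual.sum()
        spec = np.sum(~predicted & ~actual) / (~actual).sum()
        assert result.sensitivity == sens
        assert result.specificity == spec
        rest = categories == "rest"
        assert result.pct_rest_correct == np.sum(~predicted & rest) / rest.sum() * 100

    def test_zero_occurrence_activity_omitted(self):
        labels = self._labels(["running", "rest"], ["", ""])
        result = accuracy_breakdown([True, False], labels)
        assert result.activity_misclassification == {}


class TestLOOCV:
    def _df(self, participants, values, categories):
        return pd.DataFrame(
            {"participant_id": participants, "metric": values, "category": categories}
        )

    def test_identical_separable_participants(self):
        df = self._df(
            ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
            [10, 12, 1, 2] * 3,
            ["running", "running", "rest", "rest"] * 3,
        )
        result = loocv_classification(df, "metric")
        assert len(result.folds) == 3
        assert all(f.auc == 1.0 for f in result.folds)
        assert result.pooled_accuracy == 1.0

    def test_permuted_labels_null_auc(self, rng):
        n_participants, days = 20, 30
        rows = []
        for p in range(n_participants):
            for d in range(days):
                rows.append((f"P{p}", rng.normal(0, 1), "running" if rng.random() < 0.5 else "rest"))
        df = pd.DataFrame(rows, columns=["participant_id", "metric", "category"])
        result = loocv_classification(df, "metric")
        aucs = [f.auc for f in result.folds if not f.single_class]
        se = np.std(aucs, ddof=1) / math.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 0.02

    def test_too_few_groups_raises(self):
        df = self._df(["A", "B"], [1, 2], ["running", "rest"])
        with pytest.raises(ValueError, match="3 groups"):
            loocv_classification(df, "metric")

    def test_single_class_training_fold_skipped(self):
        # A holds the only running day: the A fold trains single-class and is
        # skipped; B and C folds are evaluable but their held-out days are
        # single-class, so accuracy is reported without AUC
        df = self._df(
            ["A", "A", "B", "B", "C", "C"],
            [10.0, 1.0, 2.0, 3.0, 2.5, 1.5],
            ["running", "rest", "rest", "rest", "rest", "rest"],
        )
        with pytest.warns(UserWarning, match="single-class"):
            result = loocv_classification(df, "metric")
        assert len(result.folds) == 2
        assert all(f.single_class and math.isnan(f.auc) for f in result.folds)
        assert math.isnan(result.mean_auc)


class TestAurocSampleSize:
    def test_published_medium_effect_numbers(self):
        n_pos, total = auroc_sample_size(0.6)
        assert (n_pos, total) == (129, 258)

    def test_monotone_divergence_near_null(self):
        sizes = [auroc_sample_size(a)[1] for a in (0.9, 0.7, 0.6, 0.55, 0.51)]
        assert sizes == sorted(sizes)
        assert auroc_sample_size(0.501)[1] > 100_000

    def test_independent_recomputation_at_07(self):
        # oracle: direct re-derivation of the variance-kernel formula
        def v(theta):
            return theta / (2 - theta) + 2 * theta**2 / (1 + theta) - 2 * theta**2

        z_a = stats.norm.isf(0.025)
        z_b = stats.norm.ppf(0.80)
        n = math.ceil((z_a * math.sqrt(v(0.5)) + z_b * math.sqrt(v(0.7))) ** 2 / 0.2**2)
        assert auroc_sample_size(0.7) == (n, 2 * n)

    def test_ratio_scales_total(self):
        n_pos, total = auroc_sample_size(0.6, ratio=2.0)
        assert total == n_pos + 2 * n_pos

    def test_precondition_violations(self):
        with pytest.raises(ValueError):
            auroc_sample_size(0.5)
        with pytest.raises(ValueError):
            auroc_sample_size(0.4)
        with pytest.raises(ValueError):
            auroc_sample_size(0.6, auc_null=0.7)
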