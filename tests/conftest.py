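import numpy as np
import pytest

from wristload.classification import loocv_classification
from wristload.metrics import day_metrics, metrics_frame
from wristload.processing import filter_valid_days
from wristload.synthetic import CohortConfig, generate_cohort
from wristload.training_log import label_days, labels_frame, match_days


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-scale synthetic cohort (35 x 43 days, seed 7)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Matched per-day frame plus LOOCV results for the default cohort.

    Shared session-wide because the full pipeline takes on the order of a
    minute; tests must not mutate the returned objects.
    """
    cohort = default_cohort
    valid, retention = filter_valid_days(cohort.epoch_series)
    mdf = metrics_frame([day_metrics(s) for s in valid])
    calendar = [(s.participant_id, s.date) for s in cohort.epoch_series]
    ldf = labels_frame(label_days(cohort.log_entries, calendar))
    matched, _, _ = match_days(ldf, mdf)
    cv = {
        metric: loocv_classification(matched, metric)
        for metric in ("most_active_30", "mins_ge_400")
    }
    return {"cohort": cohort, "retention": retention, "matched": matched, "cv": cv}
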