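# wristload

Wrist-accelerometer training-load analysis for runners: raw triaxial
acceleration → calibrated 5-s ENMO epochs → daily activity metrics →
ROC-cutpoint classification of running vs nonrunning days → convergent
validity of accelerometer training-load metrics against self-reported
training logs. A synthetic-cohort generator makes the full chain testable
without any real recordings.

## What it does

- **`wristload.synthetic`** — generates a cohort of runners (default 35
  participants × 43 days): per-day 17,280-epoch ENMO series built from
  per-activity intensity profiles (running 760 ± 200 mg, fast walking
  170 ± 56 mg anchors; other activities are documented, configurable
  assumptions), raw 100-Hz triaxial segments, matched training logs with an
  optional self-report error model, and ground-truth day labels.
- **`wristload.processing`** — iterative sphere-fit autocalibration from
  stationary windows, per-sample ENMO (vector magnitude − 1000 mg, truncated
  at zero) averaged over 5-s epochs, a 60-min/15-min variance-and-range
  non-wear heuristic, and the ≥ 10-h valid-day filter.
- **`wristload.metrics`** — Average Acceleration, Most Active-30mins,
  Mins≥400mg, 50-mg intensity-bin minutes between 50 and 4000 mg, and the
  WL400–4000 workload composite (bin midpoint × bin minutes).
- **`wristload.training_log`** — log parsing with row-level validation, the
  running / other-training / rest day classification (any running session
  makes a running day; multi-run days sum miles/duration and average RPE;
  training load = mean RPE × duration), and participant-day matching.
- **`wristload.classification`** — empirical ROC curves, Youden-J optimal
  cutpoints (closest-to-top-left available), accuracy breakdowns with
  per-activity misclassification, leave-one-participant-out
  cross-validation, and the Hanley–McNeil AUROC sample-size formula
  (AUROC 0.6 vs 0.5 → 129 days per group, 258 total).
- **`wristload.validity`** — OLS variance explained in miles, duration, and
  training load by Mins≥400mg and WL400–4000mg on classified running days,
  with leave-one-participant-out predicted R².
- **`wristload.pipeline`** — YAML-configured, seeded orchestration of the
  whole study with persisted intermediates and a JSON + text report.

## CLI

```sh
# full study: simulate -> filter -> metrics -> label -> classify -> validate
wristload run-all --seed 7 --out study_out
wristload --verbose run-all --config demo.yaml

# stage by stage
wristload simulate --seed 7 --participants 10 --days 14 --out data/
wristload metrics --epochs data/epochs.csv --out data/metrics.csv
wristload label --log data/training_log.csv --out data/labels.csv
wristload classify --metrics data/metrics.csv --labels data/labels.csv --out data/cutpoints.json
wristload validate --metrics data/metrics.csv --labels data/labels.csv \
    --cutpoints data/cutpoints.json --out data/validity.csv
wristload process --raw raw_segment.csv --out processed/   # raw 100-Hz path
```

All ambiguity-sensitive choices (cutpoint rule, CV unit, workload bin
representative, waking-day window, non-wear thresholds) are exposed as
config keys with the defaults documented in the module docstrings.

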