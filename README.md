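# oculokit

Analysis pipeline for clinical oculomotor assessment at 250 Hz: fixation
stability, visually guided saccades under a gap/overlap paradigm, and
sinusoidal smooth pursuit — plus a synthetic gaze-trace simulator so every
stage can be exercised and validated without patient recordings.

## What it does

- **Event detection** (`oculokit.event_detection`): parses gaze traces into
  saccades, fixations and blink spans using velocity/acceleration thresholds
  (30°/s, 8000°/s²) with configurable minimum durations and blink padding.
- **Fixation metrics** (`oculokit.fixation_metrics`): square-wave-jerk
  counting (small away/return saccade pairs within 300 ms, amplitude
  difference < 0.75°), large intrusive saccades (> 2°, blink-free), longest
  fixation period across trials.
- **Saccade metrics** (`oculokit.saccade_metrics`): time to first fixation
  within 2.5° of the target, main-saccade selection (blink / pre-target /
  displaced-start / wrong-direction filters, sixth-saccade discard rule),
  amplitude error (signed, positive = overshoot), latency with square-root
  transform and per-group ±2 SD trimming, saccade counts, gap/overlap
  contrast.
- **Pursuit metrics** (`oculokit.pursuit_metrics`): per-sample velocity gain
  against the analytic 0.25 Hz ±10° target, exclusion of saccades/blinks
  ±50 ms, tail trimming of gain to [−1, +2], pursuit saccade counts.
- **Statistics & classification** (`oculokit.stats_classification`):
  cluster-robust OLS group contrasts with an age covariate (plus
  eccentricity/condition/axis/amplitude covariates per metric),
  group × condition interaction tests, Pearson correlations with Bonferroni
  correction, Cohen's d, a > 2 SD-worse-than-controls impairment classifier,
  and accuracy-maximizing ROC cut-off selection.
- **Synthetic cohorts** (`oculokit.synthetic_data`): task schedules
  (fixation 1 + 3 trials; 4 × 10 saccade trials over 10 target locations in
  an ABBA gap/overlap block design; 2 + 6 pursuit trials), main-sequence
  saccade waveforms, group phenotype profiles (control / typical-AD / PCA)
  and fully reproducible cohort generation with ground truth.

## CLI

```sh
oculokit --seed 7 --out-dir out run-all        # simulate -> detect -> metrics -> stats -> classify
oculokit --out-dir out simulate                # traces, schedule, ground truth, pseudo-scores
oculokit --out-dir out detect                  # events CSV per trial
oculokit --out-dir out metrics                 # long-format metrics table
oculokit --out-dir out stats                   # group contrasts + gap/overlap report
oculokit --out-dir out classify                # impairment flags + ROC table
```

All stages accept `--config config.yaml` (parser thresholds, task geometry,
analysis options, profile overrides); unknown keys are rejected. See
`oculokit.io_types.load_config` for the full schema and defaults.

## Library example

```python
import numpy as np
from oculokit.event_detection import parse_trace
from oculokit.pipeline import compute_metrics
from oculokit.synthetic_data import default_profiles, make_cohort

cohort = make_cohort(default_profiles(), seed=1)
metrics, main_results = compute_metrics(
    cohort.traces, cohort.schedule, cohort.participants
)
print(metrics.groupby(["group", "metric_name"])["value"].mean())
```
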