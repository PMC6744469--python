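# oxinet

Estimation of the apnea–hypopnea index (AHI) and oxygen desaturation
index (ODI) from a single-channel pulse-oximetry (SpO2) trace, using a
small feedforward neural network — plus a synthetic annotated oximetry
cohort simulator that makes the whole pipeline testable without access
to clinical sleep recordings.

## Who this is for

Obstructive sleep apnea (OSA) severity is graded by the AHI — apneas
plus hypopneas per hour — obtained today by manual scoring of
multi-channel polygraphy, which is slow and expensive. Because
desaturation-linked hypopneas (AASM 2007 rule: ≥30% airflow drop causing
a ≥4 percentage-point SpO2 desaturation) leave a clear fingerprint in
the oximetry channel, the SpO2 signal alone carries most of the
information needed for screening. This package is aimed at researchers
in sleep medicine and physiological signal processing who want a
transparent, dependency-light reference implementation of the
epoch-regression approach: no deep-learning framework, every numerical
ingredient (including the optimizer) implemented and tested in plain
NumPy.

## Method

1. **Preprocessing** — the full-night SpO2 trace (nominally 4 Hz) is
   block-mean downsampled to 0.5 Hz and cut into 10-minute epochs with
   98% overlap (stride 12 s), giving 300-sample input vectors. Per-epoch
   targets are `6 × (number of event onsets in the window)`, i.e. the
   local event rate in events/hour.
2. **Regression network** — a 300→60→15→5→1 feedforward network with
   symmetric-sigmoid (tanh) hidden layers and a linear output, min–max
   input/target normalization to [−1, 1]. Training is full-batch
   **scaled conjugate gradient** (Møller's SCG: conjugate directions, a
   finite-difference curvature estimate along the search direction, and
   Levenberg–Marquardt-style λ adaptation), minimizing the MSE, with
   early stopping once validation MSE has failed to improve for 100
   consecutive iterations; the best-validation iterate is returned. Two
   independent networks are trained, one for AHI and one for ODI.
3. **Night-level estimate** — the full-night index is the mean of the
   per-epoch predictions, clamped at 0, and is classified into the
   standard severity grades: no OSA (AHI < 5), mild (5 ≤ AHI < 15),
   moderate (15 ≤ AHI < 30), severe (AHI ≥ 30).
4. **Evaluation** — per-patient absolute and percentage errors, the 4×4
   severity confusion matrix and accuracy, and the two-way
   random-effects absolute-agreement intraclass correlation ICC(2,1)
   with an F-based 95% CI between reference and estimated indices.

The synthetic cohort generator plants non-overlapping respiratory
events by a Poisson process, attaches baseline-to-nadir desaturations
(linear fall, exponential-shaped resaturation, circulation delay),
adds oximeter noise, integer quantization and flagged dropout
artifacts, and spans the clinical AHI range 0–150 events/hour across
all four severity classes. See `docs/methods.md` for the full model
description and its limitations.

## Worked example

```python
import oxinet as ox
from oxinet.ann import TrainingConfig

# 120 synthetic patients: 96 train, 8 validation, 16 held out
profiles = ox.sample_cohort(120, seed=42)
records, annotations = zip(*[ox.simulate_record(p, seed=100 + i)
                             for i, p in enumerate(profiles)])

model = ox.OximetryIndexModel.from_records(
    records[:96], annotations[:96],       # training nights
    records[96:104], annotations[96:104], # validation nights
    target="ahi", epoch_subsample=50)
result = model.fit(TrainingConfig(max_iterations=300, max_val_failures=100,
                                  seed=0))
print(result.summary())
report = result.evaluate(records[104:], annotations[104:])
print(report.summary())
```

This prints (about 10 s on one CPU):

```
Oximetry index regression — target AHI
--------------------------------------------------------
architecture            300 -> 60 -> 15 -> 5 -> 1
training epochs         4329
validation epochs       352
SCG iterations run      300
best validation iter    293
best validation MSE     0.0687266 (normalized)
final training MSE      0.0132096 (normalized)
stop reason             max_iterations reached

Evaluation report — AHI (N = 16 patients)
--------------------------------------------------------
mean absolute error (events/hour)        2.27
median absolute error (events/hour)      1.55
min error (events/hour)                  0.58
max error (events/hour)                  8.77
median % error                           22.4
classification accuracy                  75.0%
misclassified patients                      4
misclassified: mean absolute error       4.12
misclassified: median absolute error     2.75
misclassified: median % error            71.4
ICC (2,1)                               0.952 (95% CI 0.869-0.983)

Confusion matrix (rows: reference, cols: estimate)
                no_osa      mild  moderate    severe
      no_osa         4         3         0         0
        mild         0         4         0         0
    moderate         0         0         3         0
      severe         0         0         1         1
```

The night-level estimates track the planted ground truth to within a
couple of events/hour; the misclassified patients sit near the 5 and 30
events/hour class boundaries, where small numeric errors flip the
grade. At the package's default experiment scale (600 training / 50
validation / 100 test patients) the median absolute error drops to
~1 event/hour and severity accuracy reaches ~80–90% — run the
experiment yourself as below.

The same workflow is available from the shell:

```sh
oxinet run-all --out results/demo         # default full-scale experiment
oxinet simulate --config cfg.yaml --out cohort/
oxinet train    --config cfg.yaml --cohort cohort/ --out models/
oxinet evaluate --config cfg.yaml --cohort cohort/ --models models/ --out reports/
oxinet estimate cohort/patient_0003.csv --model models/model_ahi.json
```

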