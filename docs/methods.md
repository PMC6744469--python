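# Methods

This note documents the models and numerical procedures implemented in
`oxinet`, the assumptions behind them, the parameters that matter, and
what the synthetic experiments do and do not demonstrate.

## Problem setting

Obstructive sleep apnea produces repetitive breathing cessation events
during sleep. Severity is graded by the apnea–hypopnea index (AHI,
events/hour of recording) with class boundaries at 5, 15 and 30
events/hour, or by the oxygen desaturation index (ODI). Because
desaturation-linked hypopneas are defined by a ≥4 percentage-point SpO2
drop (AASM 2007 rule 4A), and apneas almost always desaturate too, the
oximetry channel alone carries most of the diagnostic signal. `oxinet`
regresses short windows of the SpO2 trace to local event rates and
averages those into full-night indices. The reference ("ground truth")
convention throughout is the home-sleep-apnea-test one: the index
denominator is total valid recording time, since no EEG is available
to restrict to sleep time.

## Synthetic cohort generator

Clinical oximetry datasets with manually re-scored events are not
freely distributable, so the package carries a generator whose output
has *known* per-patient AHI and ODI. It is first-class, tested code:
every pipeline result in this repository is measured on its output, and
claims must be read in that light.

### Patient profiles

`sample_cohort(n, severity_mix, seed)` draws i.i.d. patient profiles
stratified over the four severity classes. The default mix
(48.6/25.4/12.9/13.1%) reflects a suspected-OSA clinical population.
Within-class target AHI is uniform on [0,5), [5,15), [15,30) and
`30 + Exp(20)` truncated at 150 for the severe tail, spanning the
extreme clinical range (~150 events/hour). Other defaults, chosen once
as physiologically plausible values:

| parameter | default | meaning |
|---|---|---|
| `baseline_spo2` | Normal(96.5, 1) truncated [92, 99] % | awake-rest saturation plateau |
| `apnea_fraction` | Beta(2, 11) (mean 0.15) | share of events scored apnea vs hypopnea |
| `desat_yield` | Beta(8.5, 1.5) (mean 0.85) | P(event causes a ≥4-point desaturation) |
| `desat_depth_mean` | U(5, 10) points | mean desaturation depth |
| `desat_depth_sd` | U(0.5, 2) points | per-event depth spread |
| `event_duration_s` | U(15, 45) s, capped at 0.45 × cycle | respiratory event / SpO2 fall time |
| `resat_duration_s` | 20 s, capped at 0.35 × cycle | recovery time |
| `noise_sd` | U(0.2, 0.6) points | oximeter noise before quantization |
| `artifact_rate` | U(0, 1) /hour | flagged dropout runs (5–30 s) |
| `recording_duration_s` | U(6, 9) hours | ambulatory night length |

`desat_yield < 1` is what makes ODI ≤ AHI: sub-threshold events still
dent the trace (depth drawn below 4 points) but are not scored as
desaturations. The duration caps ("cycle" = 3600/AHI seconds) shorten
the event footprint for very severe patients, mirroring the short
apnea–recovery cycles of severe OSA and keeping any requested rate
feasible without event overlap.

### Record synthesis

Event count is Poisson at the target rate; onsets are placed uniformly
subject to a hard-core minimum gap of one event footprint
(event + resaturation), which preserves the Poisson count distribution
exactly while guaranteeing non-overlap. Each event produces a
desaturation starting 15 s after event onset (configurable circulation
delay): linear fall over the event duration to the nadir, then an
exponential-shaped recovery (time constant resat/3, shifted to reach
the baseline exactly at the window end). Gaussian noise is added, the
trace is rounded to integer percent (oximeter quantization) and clipped
to [1, 100], and dropout artifacts are inserted as flagged-invalid runs
(NaN samples plus a boolean mask — never a numeric sentinel value).

What the generator does **not** emulate: sleep-stage structure and
REM/NREM-dependent event clustering, position effects, central-apnea
periodic breathing, baseline drift over the night, heart-rate-linked
oximeter averaging, or non-apneic desaturations. Passing the recovery
experiments below therefore demonstrates that the pipeline is
implemented correctly and can learn the epoch-rate mapping under
realistic noise/quantization — not that clinical-data accuracy would
match.

## Preprocessing

4 Hz → 0.5 Hz downsampling is the mean of consecutive 8-sample blocks
(anti-aliasing and quantization-noise suppression in one step); a block
containing any invalid sample is invalid. Epochs are 600 s windows with
98% overlap (stride 12 s → 300-sample inputs, `n_epochs =
floor((T−600)/12)+1`); a trailing partial window is discarded because
the network input size is fixed. Epochs with more than 10% invalid
samples (configurable) are dropped; remaining invalid samples are
filled by linear interpolation so retained epochs are fully numeric.

Per-epoch targets assign an event to every window containing its
*onset* and scale the count to events/hour (×6). The hourly convention
makes the night-level aggregation a plain mean. For training pools the
`epoch_subsample` option keeps every k-th valid epoch of each record
(default experiment: k = 50, i.e. one epoch per 10 minutes of stride);
adjacent 98%-overlap epochs share 98% of their samples, so thinning
sacrifices little information while keeping desk-scale training sets
(~25k epochs for 600 nights instead of ~1.4M).

## Desaturation detector

The detector exists for ground-truth cross-checks and standalone ODI
scoring. Definition (all knobs configurable): baseline at time t is the
maximum valid sample in the preceding 120 s; a candidate opens when the
signal is ≥4 points (3 under the newer convention) below baseline; the
onset is backtracked to the last sample within 0.5 points of the
baseline (on an integer-quantized trace: the end of the baseline
plateau); the event runs while the signal stays more than 1 point below
the frozen baseline, up to a 300 s timeout or a dropout; overlapping
candidates merge. The implementation is vectorized (rolling-maximum
prefilter); the test suite holds a deliberately naive sample-by-sample
transcription of the same definition as an oracle, plus
sensitivity/PPV ≥ 0.99 checks against planted events on noise-free
simulated nights. On noisy traces the max-based baseline makes the
detector over-score shallow fluctuations; this is a known limitation —
training targets always come from annotations, never from the
detector.

## Network and training

Architecture 300→60→15→5→1; hidden activation `2/(1+exp(−2x))−1`
(identical to tanh); linear output (a sigmoid output is available as a
config switch). Inputs and targets are min–max normalized to [−1, 1]
on training data only; constant features map to 0. Initialization is
scaled-uniform `U(±sqrt(6/(fan_in+fan_out)))` with zero biases,
reproducible from a seed.

Training is full-batch scaled conjugate gradient: the curvature along
the search direction is estimated by a one-sided finite difference of
the gradient with scale σ = 5e−5, made positive definite by a
Levenberg-style λ (initial 5e−7) that is raised on poor quadratic
agreement (comparison parameter Δ < 0.25) and lowered on good
agreement (Δ ≥ 0.75); failed steps (Δ < 0) do not move the weights.
Conjugate directions restart every `n_params` iterations. The gradient
is exact reverse-mode backpropagation, verified against central finite
differences (relative error < 1e−6) across randomized architectures;
on a linear network SCG reproduces the normal-equation least-squares
solution to 1e−6, which it reaches in ≤ n_params iterations as
conjugate-gradient theory requires.

Early stopping evaluates validation MSE after every iteration: an
iteration that does not strictly improve the running best increments a
failure counter (reset on improvement); training stops after 100
consecutive failures (configurable) or `max_iterations`, and the
parameters of the best-validation iteration are restored. With the
default experiment's pool sizes, 800 iterations take ~2–3 minutes per
network on one CPU; training runs that hit the iteration cap before
the early-stop patience are normal at this scale.

Numerical edge cases: non-finite training loss aborts with the
iteration number; a vanishing search direction stops cleanly ("gradient
vanished"); negative predictions are clamped to 0 in the user-facing
per-epoch API. The night-level estimate averages the *raw* epoch
outputs and clamps the mean, because clamping each epoch first would
bias low-AHI nights upward (E[max(e,0)] > E[e] for zero-mean epoch
errors).

## Experiment design and evaluation

The default experiment simulates 750 patients (600 train / 50
validation / 100 test). The test set is chosen by sorting patients on
reference AHI and taking every k-th (k = 750//100), so it spans all
severities and nearly the full index range; the validation set is then
random. Two networks (AHI, ODI) are trained with identical machinery
and different targets. Problem sizes were chosen so the complete
experiment runs in minutes on a single CPU; they are configuration, not
method.

Evaluation reports mean/median/min/max absolute error, median
percentage error (patients with reference 0 are excluded from the
percentage median only, and the count of exclusions is reported), the
4×4 severity confusion matrix (reference rows), accuracy, the same
error statistics restricted to misclassified patients, and ICC(2,1) —
two-way random effects, absolute agreement, single rater — with the
F-based 95% CI (Satterthwaite denominator df). ICC(2,1) is the
appropriate form because scorer and network rate the same subjects and
systematic offsets should count against agreement; other forms can be
obtained from the same ANOVA table. The implementation is checked
against a hand ANOVA oracle and against an independent statistics
package.

At the default scale the synthetic recovery experiment achieves median
absolute errors around 1 event/hour, severity accuracy in the 80–90%
range, and ICC above 0.95 for both indices (see
`scripts/acceptance.py`, which recomputes these from a seed).
Misclassifications concentrate at the 5 and 30 events/hour boundaries,
and errors grow with the index because min–max target normalization
compresses the numerous low-AHI epochs relative to the rare extreme
ones.

## Known limitations

- Synthetic-to-clinical transfer is untested by construction; the
  generator's simplifications listed above all flatter the network
  relative to real nights.
- The detector's baseline convention is one of several defensible
  readings of "4% desaturation"; its parameters are calibration knobs,
  not claims about any scorer.
- Events are assigned to epochs by onset; events straddling a window
  edge contribute to windows containing the onset only.
- The per-epoch MSE is reported in normalized target space and is not
  comparable across different target scalings.
- EDF files can be read (via mne) but not written; CSV is the
  interchange format.
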