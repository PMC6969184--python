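# Methods

This note documents the models, conventions, parameters and deliberate
design choices behind `upsweep`, and what the synthetic-soundscape tests do
and do not demonstrate about field recordings.

## Signal model and feature geometry

All analysis runs at 2 kHz on mono pressure-amplitude streams in [−1, 1].
Times are seconds from stream start; intervals are half-open [begin, end).

A 2 s clip (4,000 samples) is featurized with an STFT using a 128 ms
periodic Hann window (256 samples) advanced by 50 ms (100 samples). The
framing convention starts frame k at exactly k·50 ms for k = 0…39 and
zero-pads the last frames past the clip end. This yields exactly 40 frames;
the usual ⌊(N−W)/hop⌋+1 rule would yield 38 and a non-square patch. Of the
129 FFT bins (7.8125 Hz spacing), bins 5–44 are kept: center frequencies
39.0625–343.75 Hz, which brackets the upcall band while excluding DC and
most energy above the calls. The patch is the 40 × 40 matrix of linear
magnitudes (not power, not dB), rows = frequency ascending, columns = time
ascending.

Two normalizations are provided:

- `sum_square` (the features-module default): x → x / Σx². Simple, but the
  output scale varies inversely with input gain.
- `unit_frobenius`: x → x / √(Σx²). Gain-invariant; ‖x‖_F = 1.

Zero-energy patches are passed through unchanged and flagged rather than
divided by zero.

**Classifier input scaling.** The model and pipeline layers default to
`unit_frobenius`. The reason is numerical, and matters: with `sum_square`,
the per-element scale is tied to the absolute recording level (for
unit-RMS synthetic scenes the elements are ~10⁻⁴), which leaves a
Glorot-initialized tanh network in a bias-dominated regime where short
training budgets cannot converge and the score track degenerates toward a
constant. Unit-norm inputs put typical elements at ~10⁻²–10⁻¹, where the
same budgets train to convergence and the mined "false positives with
P ≥ 0.5" are genuinely confusable events rather than arbitrary background.
Both modes remain available and a scorer records the mode it was trained
with; mixing modes at inference raises an error.

## Architectures

`lenet_variant` (default): input dropout → conv(32 filters, 5×5, tanh) →
2×2 max-pool → dropout → conv(64, 5×5, tanh) → 2×2 max-pool → dropout →
flatten (64·7·7 = 3,136) → dense(500, tanh) → dense(2) → softmax.
Max-pooling replaces classic average pooling and tanh replaces ReLU (a
ReLU switch exists). Unstated details were fixed at canonical values: 5×5
kernels, non-overlapping 2×2 pools, fully-connected width 500, and dropout
probability 0.2 at every dropout site.

`crnn`: 1-D convolution along time with the 40 frequency bins as input
channels (64 filters, kernel 3 frames) → batch norm → tanh → dropout →
GRU(64) → batch norm → GRU(64) → batch norm → dense(2) softmax on the final
time step. Batch norm tracks running moments (momentum 0.9) for inference.

Both nets output a 2-way softmax; the upcall-class probability is the
score. Softmax is evaluated in float64 at inference so easy windows do not
tie at exactly 1.0, which would make score thresholds non-separating.

## Training

Class-weighted categorical cross-entropy, with each positive example's loss
term multiplied by 3 (weighting the loss, not the sampling). Optimizer:
Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷) with per-update inverse-time decay
lr_t = lr₀ / (1 + 0.005·t) and base rate lr₀ = 10⁻³. Defaults are batch
1,000 and 100 epochs; the scaled test configurations use smaller batches
and fewer epochs (stated below). All stochastic choices — initialization,
shuffling, dropout masks — derive from one `numpy` generator seeded by
`TrainConfig.rng_seed`, so training is bit-reproducible. Replicate training
(`train_replicates`, default n = 10) uses seeds seed+0…seed+n−1 and
downstream metrics are averaged across replicates.

The networks run on a package-internal reverse-mode autodiff engine
(tensors over numpy arrays; conv via im2col; pooling with explicit argmax
scatter). Every layer's analytic gradient is verified against central
differences in the test suite.

## Dataset construction

- **Positives**: 2 s clips starting at the annotation midpoint − 1 s.
  Clips crossing a stream edge are zero-padded and flagged.
- **Random negatives**: window starts drawn uniformly from the call-free
  start set, where each candidate window dilated by a 1 s guard must miss
  every annotation. The guard (unstated in the problem definition) prevents
  near-miss leakage into the background class.
- **Augmentation**: each example re-cut from the waveform at a uniform
  shift in ±200 ms (default 1 copy per example), pooled with the originals.
  Shifting the waveform rather than rolling the patch keeps edge content
  real.
- **Hard negatives**: the stage-1 detector runs over the training streams;
  detections with P ≥ 0.5 whose peak misses every annotation dilated by the
  matching tolerance become background examples. Candidates within 0.1 s
  (one hop) of an already-pooled negative are dropped — the operational
  meaning of "not already in the training set".

Stage 2 retrains from fresh random initialization (not fine-tuning) on the
stage-1 pool plus the mined negatives.

## Detection and suppression

Windows advance by 0.1 s; each is featurized and normalized exactly as in
training (the batched implementation is contractually equal to per-window
evaluation, including the per-window zero-padded tail frames). Greedy NMS
repeatedly takes the highest remaining score ≥ 0.05 (ties to the earlier
window), emits a detection at the window center, and suppresses centers
strictly within 1 s. The 1 s radius (unstated in the problem definition) is
half the window and close to a typical call duration; it is configurable.
Consequences proved in tests: inter-detection spacing ≥ radius, and
lowering the floor only ever adds detections.

## Evaluation conventions

Matching is this package's own definition: a detection may claim an
annotation iff its peak time lies in [begin − 0.5 s, end + 0.5 s];
assignment is greedy by descending score, one-to-one, nearest-midpoint
among eligible annotations. Precision and recall are exact ratios;
undefined cases (zero denominators) are flagged, never silently zero.
Average precision uses step-wise interpolation, AP = Σ (R_i − R_{i−1})·P_i
over descending unique score thresholds — standard for detection PR curves
and conservative relative to trapezoidal areas. The workload model is
linear: review hours = (FP count + true calls) / 2,000 per analyst hour,
with 20 FP/h as the operational usefulness bound.

## Synthetic scenes

The generator emulates the statistical structure of single-sensor archival
recordings: 1/f-colored Gaussian noise band-limited to 10–800 Hz (slope 1
by default, reflecting low-frequency-dominated ocean ambient; out-of-band
components fully suppressed; unit in-band RMS), Poisson call onsets
(default 30 calls/h) with calls forbidden from overlapping each other
(upcalls are sparse contact calls), and independent Poisson confounders
(default 60/h) free to overlap anything. Calls are chirps
f(t) = f₀ + B·(t/T)^c with f₀ ~ U(55, 157) Hz, T ~ U(0.5, 2) s,
B ~ U(60, 120) Hz and c ~ U(0.8, 1.5) under a Hann envelope; the bandwidth
and curvature ranges are stand-ins chosen to keep sweeps inside the
39–344 Hz analysis band, since no quantitative envelope beyond start
frequency and duration is available. Per-event SNR is defined precisely as
the in-band (39.06–343.75 Hz) RMS ratio between the event over its own
time support and the noise floor, and each event is scaled to hit the
configured SNR (default 10 dB); a rendering-vs-remeasurement test holds
this to ±1 dB.

What the scenes do **not** model: propagation and multipath, calibrated
absolute levels, non-Gaussian noise (ice, vessels at close range), call
amplitude/SNR diversity within a scene, and real confounder statistics.
Passing the synthetic end-to-end tests therefore demonstrates that the
pipeline's machinery — features, training, mining, detection, scoring — is
correct and internally consistent at realistic SNRs, not that the shipped
defaults reach any particular performance on field recordings.

## Scaled test configurations

The end-to-end checks run at desk scale by design: synthetic call recovery
trains the LeNet variant with batch 64 for 15 epochs on ~500 examples drawn
from 30 minutes of 10 dB scenes (call rate raised to 120/h so enough
positives exist) and detects over 30 held-out minutes, requiring ≥ 90%
recall at ≤ 20 FP/h; the mining-benefit check uses five seeded runs on
8-minute confounder-rich scenes (240 confounders/h) with 10-epoch stages
and a 150-example mining cap, requiring stage-2 AP ≥ stage-1 AP in a
majority. Scene durations, rates and epoch counts for these checks are the
package's own scaling choices.

## Known limitations

- Training at the full default configuration (batch 1,000, 100 epochs) on
  large archives is slow on the numpy engine; it is intended for
  method-scale experiments, not production throughput.
- The `sum_square` normalization is faithful to its formula but couples
  classifier behavior to absolute recording level; prefer `unit_frobenius`
  unless reproducing the literal formula matters.
- The CRNN's batch-norm running statistics need a few hundred updates to
  stabilize; very short trainings can show a train/inference gap.
- Matching tolerance (±0.5 s) and NMS radius (1 s) are conventions, not
  estimates; alternative conventions can be evaluated via flags.
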