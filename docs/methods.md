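# Methods

`qeyed` detects Quiet-Eye (QE) intervals — the final, exceptionally stable
gaze fixation preceding a goal-directed action such as an arrow release —
in single-channel electrooculography (EOG). The package contains the full
chain: a generative simulator with ground-truth annotations, signal
cleaning, windowing/labeling, six per-sample detectors, and event-level
evaluation with tolerance matching.

## Synthetic EOG model

No public QE-annotated EOG corpus exists, so the package ships a seeded
generator whose output stands in for a recorded session. The signal is a
sum of four components:

* **Gaze**: piecewise-constant fixation plateaus joined by saccadic steps.
  Fixation amplitudes are Gaussian with scale `saccade_amplitude_sd`
  (default 60 µV, ≈ tens of µV per degree of visual angle for skin
  electrodes); consecutive positions are forced at least half a scale
  apart so saccades are visible. Steps are smoothed by a ~20 ms raised
  cosine, the shortest kinematics 200 Hz sampling can represent. Each shot
  contributes a saccade onto the target exactly at QE onset and a release
  saccade at QE offset. Gaze tremor is an AR(1) micro-movement whose
  standard deviation drops by an order of magnitude inside QE — the
  defining stability of the Quiet Eye.
* **Drift**: a sinusoid of amplitude 80 µV at 0.02 Hz (electrode/skin
  polarization wander, well below the 0.1 Hz analysis band). The default
  makes the raw scenario genuinely drift-dominated.
* **Blinks**: positive biphasic transients, 200–400 ms wide, 150–300 µV,
  placed by rejection sampling outside QE intervals (±300 ms margin) so
  the ground truth stays unambiguous.
* **Noise**: i.i.d. Gaussian, `noise_sd` = 3 µV; the tremor scales with
  the same parameter so the noiseless configuration degenerates to a
  clean piecewise trace.

Per shot, QE duration is uniform over 0.3–5.0 s (the range reported for
precision-aiming sports); shots are separated by a 6 s gap filled with
exploratory fixations of 0.4–1.2 s dwell. Ten participants × six shots is
the default cohort. Every quantity derives from one integer seed;
per-participant seeds are `master + index`.

What the simulator does **not** model: vertical/horizontal cross-talk,
amplifier-specific noise signatures, head movement, electrode detachment,
or any dependence of QE duration on shot outcome. Tests passing on this
generator therefore demonstrate that the pipeline recovers events whose
generative structure matches its assumptions — not performance on real
archers.

## Preprocessing

Two cleaning stages, applied per scenario (A = raw, B = bandpass only,
C = baseline removal + bandpass):

* **Baseline removal.** A 10-level discrete wavelet decomposition
  (Daubechies-4, symmetric boundary extension) puts the deepest
  approximation band at ≈ 0–0.05 Hz for 200 Hz input; that band is
  reconstructed to full length with all detail coefficients zeroed and
  subtracted from the signal. Daubechies-4 is the package default because
  its compact support tracks slow wander without smearing saccade edges;
  the mother wavelet and depth are configurable. Reconstruction is exact
  to < 1e-8 relative error (verified property), so the subtraction removes
  only what the approximation band contains.
* **Bandpass.** Order-4 Butterworth, 0.1–20 Hz (the physiological EOG
  band), in second-order sections, applied forward-backward. Zero-phase
  filtering is the default because the evaluation measures event timing to
  100 ms and a causal filter of this order would add tens of ms of group
  delay. The single-pass magnitude response leaves a 5 Hz tone within 5 %
  of unit gain and attenuates 50 Hz by > 30 dB.

## Windowing and labeling

Each annotated shot yields one analysis window from 2.5 s before QE onset
to 6 s after it — 8.5 s, i.e. exactly 1700 samples at 200 Hz. Anchoring at
the onset is the only reading of the window rule consistent with the
1700-sample segment length. Sample *i* covers `[i/fs, (i+1)/fs)` and
intervals are half-open, making mask sums and mask↔event round trips
exact. Windows that would cross a recording edge are skipped with a
warning rather than padded.

Augmentation rolls samples and mask jointly by a uniform shift (default
≤ 0.25 s) and adds Gaussian noise (default 5 % of segment SD) to samples
only. Cross-validation folds are grouped by participant — no participant
appears on both sides of a fold — which is stricter than plain
segment-level folding and removes subject leakage. Augmented copies share
their parent's participant and therefore its fold.

## Detectors

All six families map a 1700-sample window to per-sample QE probabilities,
thresholded at 0.5:

| family | architecture |
|---|---|
| `svm` | per-timepoint RBF-kernel SVM on one standardized amplitude (class-stratified subsample of ≤ 4000 training points keeps the quadratic solver tractable) |
| `cnn1d` | conv(64, k7) → conv(128, k3) → maxpool → upsample → pointwise head |
| `transformer` | conv(64, k3) → 4× pool → positional encoding → layer-norm → residual multi-head self-attention (4 heads) → residual position-wise feed-forward → upsample → head |
| `unet` | 3-level encoder (64/128/256, k3) with max-pooling, mirrored decoder with skip concatenation |
| `cnn_gru` | conv(64, k5) → BN → ReLU → conv(128, k3) → BN → ReLU → pool → biGRU(100) → biGRU(50) → dense(50) → upsample → head |
| `cnn_lstm` | conv(64, k5) → BN → ReLU → conv(128, k3) → BN → ReLU → pool → biLSTM(200) → biLSTM(100) → dense(50, L2 = 0.001 on input kernels) → upsample → head |

Design choices worth flagging:

* **Engine.** The networks run on a compact NumPy engine (`qeyed.nn`) with
  hand-written reverse-mode gradients, verified against finite differences
  for every layer. Recurrent hidden-to-hidden matrices use per-gate
  orthogonal initialization, input kernels Glorot, LSTM forget bias 1 —
  the initializations standard for these layers.
* **Time channel.** The windows are onset-anchored, so absolute position
  within a window carries label information (every true onset sits at
  2.5 s). Convolutions are shift-invariant and recurrent distance counting
  is unreliable over hundreds of steps, so the network families receive a
  second input channel holding normalized elapsed time. The SVM stays
  amplitude-only by its own definition.
* **Recurrent stack depth.** The hybrid recurrent detectors use two
  bidirectional layers followed by a time-distributed dense layer (hence
  unit counts 200/100/50 for the LSTM variant); a third recurrent layer
  added parameters without improving held-out event recovery on cohorts
  of this size.
* **Pooling.** Recurrent families pool 8× before the recurrent stack
  (40 ms resolution against the 100 ms event tolerance); the transformer
  pools 4× before attention because full 1700² attention is memory-bound.
* **Loss.** Per-sample binary cross-entropy on sigmoid outputs (computed
  from logits in stable form), Adam at learning rate 0.001 — the natural
  loss for two-class per-sample labeling. Optional positive-class
  weighting and global gradient-norm clipping exist in the config but are
  off by default (neither improved event recovery on the standard
  cohort). Normalization uses global mean/SD learned from the training
  split only. Convolution blocks follow the canonical
  conv → batch-norm → ReLU order.

## Event evaluation

Predicted masks are first cleaned morphologically: 0-gaps shorter than
100 ms (the annotation tolerance) are closed, then 1-runs shorter than
300 ms are dropped — by definition a QE fixation lasts at least ~300 ms,
so shorter candidates cannot be QE. Ground-truth masks are never cleaned.
Transitions then become events: 0→1 is an onset, 1→0 an offset, with runs
touching a segment edge clamped rather than dropped.

Onsets and offsets are matched to ground truth independently, one-to-one,
within a 100 ms tolerance applied symmetrically (`|Δ| ≤ T`; a one-sided
rule would accept arbitrarily early predictions). The matcher is an
order-preserving dynamic program that maximizes the number of matches and,
among maximum matchings, minimizes total |bias|. For symmetric tolerances
on a line an uncrossing argument shows some maximum matching is
non-crossing, so the DP is exactly optimal; the test suite verifies
equality with a brute-force bipartite oracle on thousands of random
instances. A plain nearest-neighbour greedy scan is *not* optimal here
(counterexample: truths {0, 0.08}, predictions {−0.09, 0.04}, T = 0.1),
which is why the DP was chosen.

Matched events are true positives with signed biases
(`Bias = t_pred − t_true`); unmatched predictions are false positives,
unmatched truths false negatives. Pooling onset and offset counts over all
test segments gives PPV = TP/(TP+FP), SEN = TP/(TP+FN),
F1 = 2·PPV·SEN/(PPV+SEN), plus per-sample accuracy and the mean absolute
onset/offset error in ms. Zero-denominator metrics are reported as NaN,
never as silent zeros. Cross-validation reports per-fold metrics and a
mean ± SD summary; fold results feed a two-sided paired t-test for model
or scenario comparisons (all-zero differences give t = 0; constant nonzero
differences have zero variance and are reported as undefined).

## Standard benchmark and problem sizes

`qeyed.benchmarks.standard_benchmark` is the package's study-scale run:
the default simulator (10 participants × 6 shots, 60 segments), scenario C
for CNN-LSTM, CNN-GRU and SVM, 5-fold participant-grouped
cross-validation, 30 epochs at the default batch size 8 with no validation
hold-out — the cross-validation already provides out-of-sample
measurement, and the shorter schedule keeps the full benchmark within a
desktop-CPU session; the package default remains 50 epochs, and the
CNN-LSTM in particular continues to improve slowly beyond the benchmark
schedule. No augmentation is applied (60 original segments): the
time-shift augmentation deliberately blurs the onset-position prior and
trades event-timing sharpness for robustness, which is the wrong trade
for this benchmark.

`qeyed.benchmarks.scenario_comparison` is the preprocessing ablation: the
same cohort shape with drift amplitude raised to 200 µV so the raw signal
is strongly drift-dominated, and the CNN-LSTM trained identically (12
epochs) on scenario A and scenario C input. The cleaned input yields both
markedly higher event F1 and lower onset MAE. Both runs are deterministic
in their seed.

## Numerical notes and degenerate inputs

* Thresholding is `prob ≥ 0.5`; probabilities are computed in float64 at
  predict time while training runs in float32.
* Sequence lengths that do not divide the pooling factor are zero-padded
  at the end and cropped back after upsampling.
* Wavelet depth is validated against the signal length; the error names
  the maximum feasible depth. Recordings shorter than ~40 s cannot host a
  10-level decomposition at 200 Hz.
* All-one-class training masks trigger a warning but train (the model
  then predicts the constant class).
* A zero-variance training set sets the normalization SD to 1 to avoid
  division by zero.

## Known limitations

* The simulator's QE is separable from ordinary fixations mainly through
  its stability, boundary saccades and window position; real expert
  annotations encode additional context (the release sound) that no
  signal-only detector can see. Short QEs (< 0.7 s) are the hardest case
  because exploratory fixations have similar durations.
* The SVM baseline sees one amplitude per timepoint and is essentially
  temporally blind; its role is to calibrate how much the sequence models
  gain, not to be a tuned competitor.
* Event metrics depend on the mask-cleaning minimum duration (300 ms): a
  detector that finds genuine sub-300 ms events would be penalized, which
  is intended for QE but wrong for other event types.
* Training the recurrent hybrids on a laptop-scale CPU takes a few
  minutes per fold; the engine favours clarity and determinism over
  speed.
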