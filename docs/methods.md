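# Methods

## Problem and model

The package labels each 30-s epoch of a night with a sleep stage using
only signals a wrist wearable can provide passively: an activity count
per epoch and two coarse cardiac summaries, the mean (HRM) and standard
deviation (HRSD) of instantaneous heart rate within the epoch. Staging
schemes are nested label sets — five (W/N1/N2/N3/REM), four
(W/Light/Deep/REM, with Light = N1+N2 and Deep = N3), three (W/NREM/REM)
and two (W/Sleep) — with surjective, order-consistent collapsing maps
between them.

The classifier is a sequence labeler over sliding windows of L epochs
(default 12, i.e. 6 minutes, stride 1; 9 and 15 are supported). Per
window:

1. Three 1-D convolutions (kernel 9, padding 4, stride 1, leaky ReLU
   slope 0.01) map the C input channels to F feature channels while
   preserving the temporal length (L + 2·4 − 9 + 1 = L).
2. An LSTM encoder (hidden size H) reads the L feature vectors; its
   final state initializes an LSTM decoder.
3. At each decoding step the decoder consumes the epoch's CNN feature
   concatenated with the previous context vector (input feeding).
   Multiplicative ("general") attention scores the decoder state against
   every encoder state; a softmax over scores gives attention weights,
   whose weighted sum of encoder states is the context vector. A linear
   layer on [decoder state, context] plus softmax yields the stage
   distribution for that epoch.
4. At night level, stride-1 windows give every interior epoch L
   predictions; the final label is the mode of the votes.

Channel counts follow the input variant: activity only (C=1), HRM+HRSD
(2), activity+HRM+HRSD (3, default) or those plus clock time (4).

## Training objectives

Both losses weight the categorical cross-entropy over all window epochs
(each epoch of each window is one example). IF weighting uses per-class
weights proportional to inverse training frequency. RW weighting adds a
false-positive penalty: for a true class k, predicted mass on class l≠k
is charged w_fp^{kl}·(−log(1−p_l)) with w_fp^{kl} =
sqrt((1/f_k)(1/f_l)), zero diagonal, and the false-negative vector is
w_fn = 1/f. Setting w_fp ≡ 0 recovers the IF loss, and uniform IF
weights recover plain cross-entropy; both identities are tested.

Weights are mean-normalized (mean 1; the matrix over its off-diagonal
entries) so loss magnitudes are comparable across schemes — a package
convention, chosen because nothing else pins the weights' scale.
Probabilities are clamped at ε = 1e-7 before logs.

Optimization is Adam (β = 0.9/0.999), learning rate 0.00015, batch size
50, up to 200 optimization epochs; fine-tuning re-trains all parameters
at 0.00001. The validation selection metric is weighted F1 on per-window
epoch predictions (configurable to accuracy or loss); the best snapshot
is returned. Splits are subject-wise (default 75/12.5/12.5%; train gets
floor(0.75·n), the remainder splits evenly with validation first, and
explicit held-out counts are supported for cohort-style round numbers).
Windows never cross subject-night boundaries.

## Implementation of the network

The model and both losses are differentiated by a small reverse-mode
autodiff core (`somnoseq.autograd`) over float64 NumPy arrays:
broadcasting arithmetic, batched matmul, conv1d via sliding windows, the
LSTM/attention nonlinearities, softmax, slicing/concat/stack and
reductions. Analytic gradients are verified against central finite
differences; entries whose gradient magnitude is at the finite-
difference roundoff floor are compared absolutely. Training is
deterministic given the seed on a single device.

## Preprocessing

- R-R intervals come from consecutive R-point timestamps; an interval is
  assigned to the epoch containing its terminating R-point (half-open
  30-s windows).
- Intervals < 0.33 s (spurious detections, >180 bpm) are replaced by the
  arithmetic mean of the interval and its predecessor — the only reading
  of "midpoint" that yields an interval value. Intervals > 1.33 s
  (missed beats, <46 bpm) are replaced by n = max(1, round(T/T_mean))
  equal sub-intervals of T/n seconds, T_mean being the epoch's mean raw
  interval. Single pass in input order; a first interval with no
  predecessor falls back to the epoch mean (logged).
- Instantaneous heart rate is 60/interval (bpm). Per epoch, values
  outside mean ± 2 sample SDs are discarded once and HRM/HRSD recomputed
  on the survivors (no iteration); empty epochs are masked. Sample SD
  (n−1) is used throughout; a single value gives SD 0.
- 60-s activity counts are upsampled by adjacent replication.
- Accelerometry-to-counts uses the z-axis only: a 4th-order Butterworth
  band-pass (default 0.5–3.5 Hz, configurable) removes the gravitational
  component; the absolute filtered amplitude is quantized into 128
  uniform bins over [0, 2 g] and bin indices are summed per 15-s window.
  The band edges and the binning construction are this package's
  declared conventions — the source device pipelines do not specify them
  — and are configurable rather than asserted.
- Channel alignment maximizes the cross-correlation of mean-removed
  series over ±max_lag epochs; zero-variance inputs return lag 0 with a
  warning.

## Clinical metrics

Sleep onset is the first run of three consecutive non-wake epochs — the
most stringent common definition; onset latency is its start time in
minutes. Total sleep time counts non-wake epochs; efficiency divides by
the full concurrent recording duration (an in-bed proxy). Fragmentation
is post-onset sleep→wake transitions per hour of total sleep time, and
the sleep transition index is post-onset stage-change epochs (any stage
pair, including into/out of wake) over post-onset sleep epochs — both
declared assumptions where finer definitions are not fixed. Stage times
cover all stages and sum to the recording duration; stage fractions are
over sleep epochs. Nights without onset return None sentinels, which
MAE aggregation excludes pairwise with counts reported.

Classifier metrics derive from a K×K confusion matrix (rows predicted,
columns true; display normalization makes columns sum to 100%, so a
uniform-random classifier's diagonal tends to 100/K %). One-vs-rest
sensitivity, specificity, precision, F1 and MCC are aggregated both
macro (unweighted, NaN-excluded) and weighted by true-class support;
both MCC averages are reported because usage varies.

## Synthetic nights

The generator emulates the statistical structure staging relies on, not
physiology. Hypnograms are first-order Markov chains constructed as
P = ρI + (1−ρ)·1πᵀ with persistence ρ = 0.85, so the stationary
distribution is exactly the configured stage mix (four-class default
33/47/9/11 % wake/light/deep/REM) and mean bout lengths are a few
minutes. Deep-sleep entries are modulated by exp(−deep_decay·(t/T − ½))
(default decay 1.0, centered so the night-average deep fraction stays
near nominal), reproducing the concentration of slow-wave sleep early in
the night. Emissions are stage-conditional: activity is truncated-at-
zero Gaussian, HRM/HRSD Gaussian (floored at 30 bpm / 0). Defaults place
wake high in both activity and heart rate, light/deep on an overlapping
low-heart-rate continuum, and REM with wake-like cardiac values but
near-atonic activity. Nights default to 960 epochs (8 h).

R-peak trains oscillate beat-to-beat IHR around the stage HRM as a
zero-mean sinusoid of amplitude √2·HRSD (three cycles per epoch), so
epoch means and SDs match the configured values exactly in expectation;
artifacts insert spurious beats (intervals < 0.33 s) or drop beats
(intervals > 1.33 s) with equal probability.

What the generator does not model: N1/N2 microstructure, arousals and
apnea events, circadian drift of heart rate, device-specific count
nonlinearity, missing data runs. Passing tests therefore demonstrate
that the pipeline and learner work as specified on data with the assumed
structure — not that cohort-level accuracies transfer to real wearables.

## Experiment problem sizes

The bundled experiments are scaled to single-CPU runs as the package's
own study sizes. Learning sanity: 50 subjects of 240-epoch nights,
emissions separated by ≥3–4 SDs, reduced model (hidden 32, conv width
32), 20 optimization epochs of ≤60 minibatches; mode-voted test macro
sensitivity is the outcome (≥0.85 expected; ~0.99 observed). IF-vs-RW
comparison: 24 four-class subjects of 300-epoch nights with Deep at ~9%,
18 optimization epochs of ≤60 minibatches, both losses trained on
identical data per seed, three seeds; the outcome is the mean count of
Deep false positives per loss. Transfer learning: 12 source subjects,
6 target subjects with shifted emissions (HRM +6 bpm, activity ×1.6),
10 optimization epochs; fine-tuned vs directly-trained target accuracy,
averaged over 5 seeds.

## Known limitations

- The attention variant, hidden sizes (default H=128, F=64), decoder
  input scheme and clock encoding (seconds since midnight scaled to
  [0,1], not z-scored) are declared package defaults where the
  underlying method description leaves them open; all are configurable.
- The short-interval midpoint rule is applied once; adversarial chains
  of sub-0.33-s intervals could still leave short outputs (they are then
  handled by the 2-SD rejection).
- Sleep efficiency uses recording duration, not a scored in-bed period.
- CPU-scale NumPy training is intended for the bundled experiment sizes;
  cohort-scale training (hundreds of 960-epoch nights, 200 optimization
  epochs) would need a GPU framework implementation of the same
  architecture.
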