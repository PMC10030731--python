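# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices, and the points where the design was genuinely open.

## Signal model and preprocessing

A recording is a channels × samples array in microvolts at 1,000 Hz,
four channels (TA, LG, MG, SOL). Preprocessing is causal by default —
2nd-order IIR notch at 50 Hz (quality factor Q = 30, chosen to reject
the power line while leaving the 20–450 Hz band essentially untouched)
followed by a 4th-order Butterworth band-pass, 20–450 Hz. A zero-phase
forward–backward option (`zero_phase=True`) exists for offline analysis;
the causal default reflects the real-time control setting the decoder
targets. Filtering is linear, so amplitude information is preserved.

Per-channel z-normalization (`normalize`) is implemented, tested and
composable (it records the pre-normalization σ per channel so that
amplitude thresholds keep their physical meaning), but the experiment
pipeline computes features on the **filtered, un-normalized** signal.
This is a deliberate and load-bearing choice: per-trial, per-channel
z-scoring forces every window's RMS to ≈ 1, erasing both the amplitude
scaling that the load classifier needs and the per-channel amplitude
pattern that distinguishes movements in the synthetic data. With
normalization in the feature path, the first classification step would
be impossible in principle, not merely harder.

### Windowing

Two levels: 210 ms analysis windows slid by 120 ms within each trial
(windows never span trial boundaries), and 20 ms sub-windows slid by
10 ms inside each analysis window — (210 − 20)/10 + 1 = 20 sub-windows.
Trials contribute their trimmed active segment only: of the 1 s motion +
3 s hold phase, 200 ms are dropped at each end, leaving 3.6 s and hence
29 windows per trial by inclusive enumeration.

`eq3_sample_count` implements the bookkeeping rule
floor((T − window)/slide) **without** the +1 of inclusive enumeration;
applied to the concatenated effective duration of one subject under one
load (6 movements × 12 repetitions × 3.6 s = 259.2 s) it yields 2,158
windows. Both conventions are kept and their off-by-one relation is an
explicit tested invariant; the floor rule is used for sample accounting,
the inclusive per-trial enumeration for actual segmentation (the
concatenated-duration arithmetic would otherwise let windows mix
movements).

## Time-domain features

Eight features per 20 ms sub-window per channel, canonical definitions:
RMS, MAV, WL, ZC (sign change **and** |Δ| ≥ t), SSC (slope product
≥ t), unbiased variance (divisor M − 1), LogD = exp(mean ln(|x| + ε))
with ε = 1e−12 guarding zeros, and WA (|Δ| ≥ t). The amplitude threshold
t defaults to 50 μV and is interpreted on the raw microvolt scale; when
features are computed on a normalized window the threshold is divided by
that channel's stored pre-normalization σ, so the gate corresponds to
the same physical amplitude either way. Feature order is fixed
(RMS, MAV, WL, ZC, SSC, VAR, LogD, WA) regardless of selection order.

## Boruta feature selection

Shadow features are independently permuted copies of each candidate
column; permutation preserves the marginal distribution while destroying
any association with the labels, making the best shadow a data-driven
importance null. Per iteration a random forest (200 trees) is fit on
the augmented table and each column receives a Z-score: mean per-tree
importance divided by the standard deviation of per-tree importances.
Per-tree importance is the classic out-of-bag permutation importance
(accuracy decrease on the tree's OOB samples when the column is
shuffled). This signed importance is essential: impurity-based
importance is strictly positive, so its mean/sd ratio is ≈ 1/CV for
informative and useless columns alike and the comparison against the
best shadow loses all power.

A real feature scores a hit when its Z exceeds the maximum shadow Z.
After every iteration a two-sided binomial test (α = 0.05) against the
fair-coin null marks features important (significantly more hits) or
unimportant (significantly fewer; such features leave the table for
later iterations). The loop stops when nothing is tentative or after
`max_iter` (default 100) iterations; leftover tentative features are
excluded from the resulting feature set by default (conservative).

Two practical details:

- Shadows are padded to at least five even when fewer candidates remain,
  because the maximum over very few shadows is a weak null — a fixed
  noise column's spurious in-sample correlation with the labels would
  beat it too often.
- A pure-noise column is *exchangeable* with every shadow, so it beats
  the maximum of S shadows with probability ≈ 1/(S+1) per iteration;
  single-iteration "noise below the best shadow" statements therefore
  hold at the ~1 − 1/(S+1) level, not at an arbitrary confidence. The
  binomial test across iterations is what turns this into reliable
  unimportant calls.

## Load stage

The per-channel RMS of the full 210 ms window (computed on the filtered,
un-normalized signal) feeds a random forest (200 trees, unlimited depth,
seeded) over the three load classes. RMS tracks contraction intensity
and hence external load; this is the entire first step of the decoder.

## CNN-LSTM movement classifier

Architecture (features mode, N selected features): per LSTM time step,
each of the four channels owns a branch — conv1d 32 filters kernel 3,
ReLU, conv1d 32 filters kernel 2, ReLU (both length-preserving "same"
convolutions; the even kernel pads one sample on the right), max-pool 2
(floor division for odd lengths), flatten. Branch outputs concatenate:
4 × (5 × 32) = 640 per step. The (20, N) per-channel feature matrix is
split into halves — sub-windows 1–10 and 11–20 — forming the two time
steps of a 50-unit LSTM; only the final hidden state is used, then
dropout 0.6, dense 100 + ReLU, dropout 0.6, dense 6 + softmax.

Parameter accounting is closed-form and exact per layer: conv =
kernel × in_channels × filters + filters; LSTM = 4 × ((input + units) ×
units + units) (single bias per gate); dense = in × out + out. With
N = 7: 4 × 704 + 4 × 2,080 + 138,200 + 5,100 + 606 = 155,042. In raw
mode each channel's step input is 25 samples × 1, giving 128-parameter
first convolutions, a 1,536-wide concatenation, a 317,400-parameter
LSTM, and 331,938 in total. The second convolution's kernel is 2, not 3:
the published per-layer count (2,080) admits only kernel 2, and the
totals reproduce exactly under that reading.

Raw mode maps a 210-sample window to 2 × 25 samples per channel by
splitting into 105-sample halves and polyphase-resampling each to 25
(up 5 / down 21). The choice of resampling is this package's own; it
reproduces the parameter accounting, which is what raw mode exists for
here.

Training: Adam, learning rate 0.001, batch 256, 100 epochs by default,
cross-entropy loss L = −N⁻¹ Σᵢ Σ_c y_ic log p_ic (ε = 1e−12 guards
log 0). Inputs are standardized per (step-position, feature, channel)
using training-set statistics inside the estimator — the features span
six orders of magnitude (variance in μV² vs counts ≤ 19), and a fixed
affine transform preserves all class information while making
optimization stable. Dropout uses inverted scaling and is inactive at
inference. Everything is seeded; two fits with the same seed produce
bitwise-identical loss histories. The implementation is pure NumPy with
hand-derived backward passes, verified against finite differences in the
test suite.

Class order is fixed as PF, DF, IV, EV, IR, ER (labels 0–5); load order
low, medium, high.

## Two-step decoder and experiments

`TwoStepClassifier` holds the load forest and one fitted movement model
per load; prediction routes each window's feature tensor to the model of
its predicted load (oracle-load routing is available for ablation). The
experiment harness splits each load's windows 8:2 (training count =
floor(0.8 n), stratified by movement; a stratified k-fold helper is
provided for within-training validation), trains one movement model per
load, and reports:

- **one-step**: the 3×3 matrix of accuracies, model trained under load i
  tested under load j; diagonal = intraload, off-diagonal = interload,
  plus means/sds and the overall mean over all nine cells;
- **two-step**: end-to-end routed accuracy on the pooled held-out set,
  with the movement confusion matrix and per-true-load accuracies.

`run_full_comparison` trains the per-load models once and evaluates both
protocols on the same splits, so the comparison isolates the routing.

## Synthetic data

`generate_trial` emulates the acquisition protocol: 4 s rest, 1 s
motion, 3 s hold, 4 s rest at 1 kHz. The signal is Gaussian white noise
shaped by the same 20–450 Hz band-pass the pipeline uses (the shaping
filter's white-noise gain is computed from its frequency response so the
active-phase standard deviation is exact), with:

- a 6 × 4 gain matrix (μV) giving each movement a distinct per-channel
  amplitude pattern, loosely guided by which muscles drive each
  rotation (TA in dorsiflexion/inversion, the triceps surae in
  plantarflexion); defaults span 30–150 μV;
- load scales (1, 3, 9) multiplying all gains — the roughly threefold
  stiffness steps between load levels;
- baseline noise σ = 10 μV during rest;
- 50 Hz sinusoidal interference (20 μV, random phase per channel), on by
  default so the notch stage is exercised end to end;
- per-subject multiplicative log-normal gain jitter (σ = 0.1).

The generator reproduces the statistical structure the decoder relies on
(band-limited spectra, movement-specific channel patterns, load-scaled
amplitudes, balanced labels, seeded determinism). It does **not** model
motor-unit physiology, amplitude non-stationarity within a contraction,
fatigue, electrode shift, or crosstalk; passing tests demonstrate the
pipeline's correctness and the load-variation phenomenon under the
stated amplitude model, not performance on recorded human data. The
amplitude defaults are stated as plausible rather than calibrated — no
quantitative amplitude description of real subjects was available to
calibrate against.

## Problem sizes

Tests run the pipeline at desk scale: the shared test dataset is one
synthetic subject × 2 repetitions (36 trials, 1,044 windows, 10 epochs),
and the end-to-end comparison uses one subject × 4 repetitions
(72 trials, 2,088 windows, ≤ 30 epochs), sizes at which every stage's
behavior (perfect intraload decoding, collapsed interload transfer,
near-perfect load routing) is already fully expressed. The acceptance
script uses the same 72-trial setting.

## Known limitations

- The NumPy network is CPU-only and single-threaded beyond BLAS; it is
  sized for the 155k-parameter architecture, not for large models.
- Normalization statistics are per-trial; using training-set statistics
  only (to avoid any leakage across the split) would be the stricter
  protocol for real data. With per-trial statistics the question is moot
  here because the feature path skips normalization.
- The deposited human dataset's internal layout is undocumented; no
  loader is provided, and the study's human-data accuracy figures are
  outside what synthetic data can or should reproduce.
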