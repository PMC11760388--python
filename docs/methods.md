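# Methods

This note documents the models, algorithms and design choices of `ecgcl` at
the level a maintainer or reviewer needs: what is computed, under which
assumptions, and where the genuinely open choices were resolved.

## Problem setting

Binary AF detection on single-lead 30 s ECG segments sampled at 128 Hz
(`T0 = 3840` samples). Atrial flutter is grouped with AF as the positive
class; every other rhythm is non-AF. Training data are segment *pairs*:
the analysis lead plus a simultaneously recorded second lead of the same
window. Labels may be present (labelled set) or absent (unlabelled set);
pre-training consumes both.

## Preprocessing

Fixed stage order: resample → band-pass → segment → label → z-score → bSQI
filter. Re-running on identical input is bit-identical (no randomness).

* **Resampling** — polyphase FIR (`scipy.signal.resample_poly`) with the
  rational rate ratio; identity when the rate already matches.
* **Band-pass** — 4th-order Butterworth, 0.5–40 Hz, applied
  forward-backward (zero phase). DC maps to ~0; a 10 Hz tone keeps its RMS
  within 5 %; a 60 Hz tone is attenuated below 0.1 RMS.
* **Segmentation** — windows start at 0 with step = window − overlap
  (30 s windows, overlap 0 or 15 s); trailing parts shorter than one
  window are discarded, so a record of `L` samples yields
  `floor((L − win)/step) + 1` windows.
* **Labelling** — a window is AF iff AF/AFL rhythm annotations cover at
  least 50 % of its duration. The majority-duration rule is symmetric; the
  tie (exactly half) counts as AF. Coordinates are 0-based samples,
  intervals half-open `[start, end)` throughout the package.
* **z-score** — population (1/N) standard deviation; a constant window
  maps to zeros and raises a flag instead of dividing by zero.
* **bSQI** — agreement of two independent beat detectors on the same
  segment, `matched/(nA + nB − matched)`, greedy one-to-one matching
  within 150 ms. Detector A is the Pan–Tompkins-style pipeline below;
  detector B finds local maxima of the 150 ms moving-average *energy*
  envelope (squared, median-removed signal) above a relative floor
  (half the median energy of the prominent peaks). Squaring suppresses
  P/T/f waves by the square of their amplitude ratio to the QRS, which is
  what makes B informative yet independent of A's derivative pipeline.
  Unmatched beats within 150 ms of a window edge are excluded from both
  counts: a boundary-truncated beat is not evidence about signal quality.
  Segments with bSQI < 0.8 are discarded; when both detectors return
  nothing the index is 0 with a degenerate flag. bSQI is computed on the
  band-passed, pre-normalisation signal; both detectors are
  amplitude-scale invariant, so this placement is immaterial.
* **QRS detection** — band-pass 5–15 Hz → derivative → square → 150 ms
  moving-window integral → adaptive signal/noise threshold
  (`thr = noise + 0.25·(signal − noise)`, exponential updates) with a
  250 ms refractory, followed by refinement to the nearby extremum of the
  band-passed signal. All thresholds are relative to the data, so
  detections are invariant under amplitude scaling; a flat signal returns
  an empty list. On clean synthetic records every beat is found within
  ±40 ms (in practice within ±1 sample).

## Synthetic data generator

The generator is first-class, tested code; it defines the study conditions
for every empirical test in the package.

Each beat is a superposition of Gaussian bumps placed relative to the R
peak: Q (−40 ms, width 20 ms, −0.15), R (0, 20 ms, +1.0), S (+40 ms,
20 ms, −0.25), T (+200 ms, 50 ms, +0.35), and for non-AF a P wave
(−160 ms, 25 ms, +0.15 by default). RR intervals are truncated-normal
(mean 0.8 s by default, coefficient of variation 0.05) for non-AF and
truncated-uniform over ±40 % of the mean for AF (CV ≈ 0.23); all intervals
respect a 0.25 s refractory floor. AF adds a 6 Hz sinusoid of amplitude
0.1 (within the physiological 4–9 Hz fibrillatory band, a tenth of the R
amplitude) with a per-beat random phase. Lead 2 is a gain-scaled (0.7)
copy with the T amplitude halved — same rhythm, different morphology,
which is exactly the invariance the channel objective is meant to
exploit. Gaussian observation noise (sd 0.05 by default) is added per
lead. Dataset records draw their mean RR uniformly from 0.6–1.0 s so the
classes cannot be told apart by heart rate alone.

What this emulates: the three AF hallmarks (RR irregularity, absent P,
f waves), exact R ground truth, and a two-lead structure. What it does
not: ectopic beats, noise bursts and electrode artefacts, inter-subject
morphology variation, class imbalance, or any physiologic coupling between
rate and morphology (it is a template model, not a dynamical one). Passing
the benchmark therefore shows the *machinery* learns the intended
invariances under controlled conditions; it is not evidence about clinical
performance on real recordings.

## Encoder

`f` — input convolution (kernel 7, stride 1) into `c0` channels, then six
residual blocks. Each block: convolution (kernel 3, stride 2) → ReLU →
convolution (kernel 3, stride 1), plus a shortcut (1×1 stride-2 projection
when the channel count changes, strided identity otherwise), ReLU after
the sum. No normalisation layers inside the blocks; He initialisation.
Total downsampling 2⁶ = 64, so `T0 = 3840` gives `T = 60` hidden
timesteps. Default channel plan (32, 64, 64, 128, 128, 128), `Dh = 128`.

`g` — one forward and one backward LSTM over the hidden sequence, 128
units per direction (`Dz = 256`). The encoder representation is the fused
sequence's final element: the forward state after the whole sequence
concatenated with the backward state at the last position (which, by
definition of the reversed recurrence, has consumed exactly that last
timestep), then L2-normalised (ε = 1e-12). Before the LSTMs each hidden
vector is direction-normalised (unit L2 norm): the temporal objective on
`h` is cosine-based and therefore scale-free, and bounded inputs keep the
LSTM gates out of saturation — without this the post-ReLU feature
magnitudes (order 10) saturate every gate and the fusion network is
untrainable in practice. LSTM biases: forget gate 1.0, candidate gate 0.1
(so even an all-zero hidden input produces a well-defined, bias-driven
state rather than an exactly zero vector).

Classifier — `Dz → 128 → 64 → 2`, batch-norm before each ReLU. During
training batch statistics are used; for inference the statistics are
frozen from a pass over the training representations. An optional
projector (two affine layers with ReLU, output size = input size) can be
enabled for ablations; it is used only inside the channel/label losses
during pre-training and discarded downstream. Default: off.

The whole stack is numpy + `autograd` (reverse-mode AD). The 1-D
convolution is registered as a custom primitive with hand-written
vectorised VJPs; the generic autograd slice-gradient path is orders of
magnitude too slow at signal length.

## Objectives

Cosine similarity is used in all three losses (on unit-norm `z` it equals
the dot product). Log-sums are stabilised by per-anchor max subtraction;
excluded terms are masked at −1e9 before exponentiation.

* **Temporal**: for anchor `(i, t)` the positive is the other view at the
  same timestamp; the denominator sums the cross-view similarities at all
  timestamps plus same-view similarities at `t′ ≠ t`; average over batch
  then timesteps. `τ = 1.0`. At `B = T = 1` the loss is exactly 0.
* **Channel**: positive is the second lead of the same window; denominator
  sums both leads of all batch members (excluding the anchor itself in the
  same-lead part); the upper summation limit is the batch size. `τ = 0.1`
  in training; closed forms in the tests use `τ = 1`.
* **Label** (supervised contrastive): per anchor, the mean negative
  log-probability of its same-label positives against all other samples.
  Anchors with no positive contribute nothing and are excluded from the
  outer mean; an all-singleton batch gives 0 with a warning. By default
  the loss sees the 2B multiview set (weak + strong encoder
  representations, labels duplicated); `label_loss_views="single"`
  restricts it to the weak views.
* **Combination**: `λ = (⅓, ⅓, ⅓)` labelled, `(½, ½, 0)` unlabelled; the
  weights are validated to be convex. The channel loss consumes the weak
  views of both leads.
* **Cross-entropy** (downstream): softmax probabilities clipped to
  `[1e-7, 1 − 1e-7]`, then the per-class binary form
  `−Σ_i [y_i log y′_i + (1 − y_i) log(1 − y′_i)]`, batch-averaged.

Every loss has an independent nested-loop reference implementation in the
test suite; agreement is required to 1e-6 relative error.

## Training procedure

**Pre-training** — Adam, initial learning rate 1e-3, step decay ×0.8 every
3 epochs; default 40 epochs, batch 256. Each step draws a batch from a
single source (labelled or unlabelled); the two sources are interleaved
deterministically in proportion to their batch counts (merge by fractional
position). The strong view is built per sample with independent beat
selections and flip draws; R peaks come from generator ground truth when
available and from the QRS detector otherwise. Runs are deterministic
given the seed (single-threaded numpy).

**Fine-tuning** — Adam with `η(T_cur) = η_base/(1 + 10·T_cur/T_max)²`
applied per epoch, `η_base = 1e-3`, default `T_max = 30`, batch 512. No
augmentation downstream. Linear probing trains only the classifier on
representations computed once from the frozen encoder (frozen bit-exactly,
asserted in tests); full fine-tuning updates encoder and classifier
jointly. Evaluation uses a stratified 70/30 held-out split and reports
accuracy plus macro-averaged sensitivity, precision and F1 from the
confusion matrix (zero-denominator cells count as 0).

## The synthetic benchmark

`ecgcl.benchmark.run_synthetic_benchmark` is the package's end-to-end
check: 512 labelled + 512 unlabelled pairs (half AF), 5 pre-training
epochs of a reduced encoder (channel plan (8, 16, 16, 32, 32, 32),
`Dz = 64`), then linear probe, full fine-tune and a random-encoder probe.
Batch sizes are scaled to the dataset — 16 for pre-training, 128 for
fine-tuning (30 epochs, the downstream default) — because at this data
volume the full-scale batches would leave only a handful of gradient
steps per run; with them the benchmark finishes in a few minutes per seed
on one CPU.  During pre-training the weak view, strong view and second
lead are stacked into a single forward pass (one autograd graph per step
instead of three).
Sub-seeds (data, pre-training, fine-tuning, random baseline) are spawned
from the benchmark seed. The representation margin is the mean
within-class minus between-class cosine similarity of held-out `z`.

## Numerical choices and degenerate inputs

* float32 parameters and activations; float64 in the signal-processing
  path.
* Masked similarities at −1e9 (exp underflows to exactly 0); L2
  normalisation ε 1e-12; softmax probability clipping 1e-7.
* Constant segments z-score to zeros (flagged); flat signals yield empty
  beat lists; empty∧empty detector output gives bSQI 0 with a degenerate
  flag; `t_wave_mask` without R peaks warns and passes the signal through.
* Mask windows use `floor(offset·fs)` sample offsets and half-open
  intervals, so masked-sample counts are exact (32 per beat at 128 Hz);
  windows are clipped at the segment end.
* The mask fill value is 0 — the baseline of a z-scored signal.

## Known limitations

* The generator's simplifications (above) bound what the benchmark can
  claim; real-data performance must be established on real WFDB corpora,
  for which the I/O path (formats 16 and 212, MIT annotation files) is
  provided but no download tooling is.
* The WFDB reader covers the common single-file, format-16/212 layout of
  the targeted AF databases, not the full format family (no multi-frame
  skew/offset handling, no format 80/212-variant zoo).
* Training is CPU-bound numpy; the default-size encoder trains at
  research-code speed, not framework speed. The architecture details the
  source text leaves open (kernel sizes, strides, channel counts, residual
  internals, classifier widths) are fixed here as declared above so that
  every shape in the tests is exact.
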