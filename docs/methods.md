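# Methods

## Problem setting

Single-trial classification of left- versus right-hand motor imagery
from multichannel EEG, in the regime typical of clinical
brain–computer-interface rehabilitation work: small per-subject
datasets (~100 trials), many subjects, and substantial inter-subject
variability.  The package implements the full chain — signal
simulation, preprocessing, a compact two-block CNN, per-subject
training, transfer learning by layer freezing, and evaluation — and is
designed so that every stage is testable without access to clinical
recordings.

## Synthetic signal model

No public dataset accompanies the acquisition protocol this package
targets (64 channels, 960 Hz, 6 s task epochs, ~100 trials per subject,
cohorts of patient-like and healthy-like subjects), so the generator
produces trials from an explicit statistical model:

* **Background**: independent per-channel power-law noise with power
  spectrum ∝ 1/f² above 1 Hz (flat below), normalized to unit variance
  per channel.  The exponent concentrates background power at low
  frequencies, as in resting EEG, and keeps the 8–13 Hz band share of
  background power small (~2%).
* **Common-mode alpha**: a weak sinusoid at the mu frequency shared by
  all channels (amplitude 0.05 relative to mu).  Its role is spatial
  correlation, not power; keeping it weak preserves the lateralized
  band-power contrast below.
* **Sensorimotor rhythm**: on two disjoint lateral channel groups
  (default: two blocks of 8 channels, a hand-motor-strip analogue), a
  mu-band sinusoid at `mu_freq` (default 10 Hz) plus a half-amplitude
  first harmonic at `2·mu_freq`.  The harmonic reflects the arch-shaped
  (non-sinusoidal) mu waveform, whose spectrum carries substantial beta
  power — and it is what survives a 12–32 Hz band-pass, making the
  decoding task learnable through the package's own preprocessing (the
  10 Hz fundamental is ~25 dB down after the zero-phase filter).
  Channel gains within a group are fixed per subject (uniform 0.8–1.2);
  phases and a lognormal amplitude jitter (σ=0.1) vary per trial.
* **Event-related desynchronization (ERD)**: the single class-dependent
  feature.  For a given trial the sensorimotor amplitude on the group
  *contralateral* to the imagined hand is multiplied by
  `(1 − erd_depth)`.  At `erd_depth = 0` the two classes are
  identically distributed by construction.
* **Mains interference**: an optional sinusoid at `line_freq`
  (default 50 Hz, amplitude 0.1 relative to mu) on all channels.

`snr_db` (default 5 dB) sets the power of the mu fundamental per
lateral channel over the unit-variance background.  Under these
defaults the Welch band-power ratio between the attenuated and
unattenuated condition reproduces `(1 − erd_depth)²` to within ~10%,
dominated by the small in-band background share; the test suite checks
a 15% tolerance.

Cohorts add subject-level jitter: mu frequency (sd 0.5 Hz), SNR
(sd 1 dB) and ERD depth (sd 0.05), with patient-like subjects drawn at
0.15 lower mean ERD depth and 3 dB lower SNR — encoding that patient
EEG is noisier and carries weaker sensorimotor modulation, which makes
patient subjects measurably harder to decode.

**What the generator does not emulate**: volume conduction through a
head model, non-stationary ERD time courses, ocular/muscular artifacts,
electrode drift, or inter-channel background correlation.  Passing
tests therefore demonstrate that the pipeline recovers a lateralized
band-power contrast under realistic noise levels — not performance on
clinical recordings.

## Preprocessing

An order-4 Butterworth band-pass (12–32 Hz) applied forward and
backward (`sosfiltfilt`), then polyphase decimation 960 → 60 Hz
(`resample_poly`, Kaiser-windowed FIR, linear-extension padding).
Numerical properties, measured on the designed filter:

| probe | power gain (zero-phase) |
| --- | --- |
| 5 Hz | −88.7 dB |
| 10 Hz | −24.8 dB |
| 15–28 Hz | ≥ −0.6 dB |
| 50 Hz | −52.5 dB |

Choices worth recording: the two corners printed for the "low pass"
filter imply a band-pass, which is what is implemented; the band-pass
runs *before* decimation because its 32 Hz corner exceeds the
post-decimation Nyquist (30 Hz); zero-phase filtering avoids
class-correlated phase distortion; filtering is per epoch (6 s at
960 Hz leaves ample samples relative to the filter's group delay, and
the implementation refuses trials shorter than three padding lengths).
Output length is `floor(S_in · fs_out / fs_in)` — 360 samples for a 6 s
trial — and depends only on geometry, never on data values.

## Architecture

`(M, S)` input → temporal convolution (T=8 filters, kernel (1, 64),
'same' padding, linear) → batch norm → depthwise spatial convolution
(kernel (M, 1), depth multiplier DP=3, collapsing the electrode axis)
→ batch norm → ReLU → max-pool (1, 4) → dropout 0.6 → separable
convolution (depthwise (1, 16) + pointwise into P=12 maps) → batch
norm → ReLU → max-pool (1, 6) → dropout 0.6 → flatten →
dense softmax (K=2) under a max-norm 0.25 constraint on each output
unit's incoming weight vector.

Closed-form shapes at (M=64, S=360): 8×64×360 → 24×1×360 → 24×1×90 →
12×1×90 → 12×1×15 → 180 features → 2; total 3 214 parameters, 362 of
them in the classifier.  The flatten width is `P·⌊S/24⌋`, the
composition of the two pooling stages — property-tested across random
configurations.

Design notes.  Dropout defaults to 0.6 in both blocks (the tuned
value), with per-block overrides.  Pooling is max pooling; activations
are ReLU; the loss is cross-entropy on softmax outputs.  The depthwise
kernel spans all M electrodes, the only reading consistent with the
printed (DP·T)×1×S output shape.  'Same' padding keeps the printed
widths exact.

The network, its gradients and Adam are implemented directly on numpy
arrays.  The temporal convolution's forward and backward passes run as
frequency-domain products (FFT length covering the full linear
convolution, so the result is exact to float rounding); every backward
pass is pinned by central-difference gradient checks, and the
closed-form complexity census is cross-checked against the
instantiated parameter arrays.  One consequence worth knowing:
bias terms feeding directly into a batch-norm layer are redundant
(their gradient is ~0); they are kept for structural fidelity.

## Training

Adam (β₁=0.9, β₂=0.999, ε=1e-8) at learning rate 2e-4 for 200 epochs
(defaults), batch size 16 (not specified anywhere; chosen for ~100-trial
datasets), shuffled per epoch, max-norm re-applied after every step.
The returned weights are those of the best validation-accuracy epoch
(ties → earliest).  A zero learning rate is an evaluation-only pass: no
parameter or batch-norm-statistics updates, which the fine-tuning
protocol uses as its no-op contract.

Splits: stratified 70/15/15 with largest-remainder rounding (at N=100:
70/15/15 — the printed 90/15/15-of-100 is arithmetically impossible, and
this choice preserves the 15/15 validation/test sizes).  Stratified
K-fold cross-validation (K=12) is the alternative evaluation mode; each
fold carves its own validation share out of the training portion.
Fixed-split and cross-validated evaluation are deliberately independent
modes rather than nested.

## Transfer learning

`pretrain_source` trains one model on pooled trials of the source
subjects.  `apply_scheme` derives a target model: E1 re-initializes all
three parameter groups (from-scratch baseline), E2 freezes block 1,
E3 freezes both blocks; `classifier_only` is E3 with a fresh head, and
`full_finetune` freezes nothing.  Freezing includes batch-norm running
statistics — the strict reading of "unchanged" — and is verified
bit-exactly in tests.

`finetune_target` runs a two-stage protocol: (1) classifier-only
adaptation at the base learning rate (20 epochs default), then
(2) the scheme's trainable groups continue at 0.1× the base rate for
50 epochs (both quantified here; only "comparatively low" is specified
upstream).  On synthetic cohorts sharing the lateralized-ERD structure,
E2 matches or beats E3 on average — the frozen spatial filters transfer,
while block 2 retains room to adapt to subject-specific rhythm
frequencies.  This ordering is a statistical property over subjects,
not a per-run guarantee.

## Evaluation

Sensitivity and specificity are computed in two labeled modes: the
non-standard definitions with FP (resp. FN) in the denominator, kept
verbatim because the published worked example depends on them, and the
conventional definitions.  They coincide exactly when FP = FN.  Cohen's
kappa comes from the confusion marginals; "mean squared error" is the
Brier score between one-hot labels and softmax outputs (sum over
classes, mean over trials).  The paired t-test on per-subject
accuracies is two-sided (`scipy.stats.ttest_rel`), with identical
vectors defined as (t=0, p=1) and zero-variance nonzero-mean
differences rejected as degenerate.

Complexity is reported as one multiply-accumulate per kernel tap per
output element for convolutional and dense layers (normalization,
pooling, activations: zero), plus a parameter census; the convention
string is embedded in every report because "FLOPs" figures are
meaningless without one.  Under this convention the default
architecture costs 12.41 M MACs per trial, dominated by the temporal
convolution (11.80 M = 8·64·64·360).

## Problem sizes used in tests and the acceptance script

The end-to-end experiments run at a reduced scale chosen to keep the
whole suite fast while leaving the contracts unchanged: 16-channel
montage (two 4-channel lateral groups), 100 trials per subject,
60 training epochs, three seeds for decodability; and an 8-subject
cohort (3 source, 5 target) with 80 trials per subject, 40 pretraining
epochs and a 15+30-epoch fine-tuning schedule for the transfer
comparison.  At this scale the strong-ERD subject (erd_depth 0.7,
5 dB SNR) decodes at ≥0.85 mean test accuracy and the no-ERD control
stays in the chance band.

## Known limitations

* Batch-norm statistics make evaluation depend on training history;
  two models with identical weights but different running statistics
  can disagree.
* The generator's stationary sinusoidal rhythm is easier to decode
  than real ERD at matched SNR; absolute accuracies here should not be
  compared with clinical results.
* The EDF exporter quantizes to 16 bits against a symmetric physical
  range chosen from the data; datasets with extreme outliers lose
  resolution on typical samples.
* Cross-validation retrains from scratch per fold; at K=12 this is the
  dominant cost of the pipeline.
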