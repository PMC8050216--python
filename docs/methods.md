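# Methods

## Problem and model

Sleep staging partitions an overnight polysomnogram into a sequence of
stages {W, N1, N2, N3, REM}, conventionally one label per 30-s epoch.
somnoseg implements a fully convolutional segmentation approach: a 1-D
U-Net maps a two-channel (EEG + EOG) signal at a fixed internal rate of
128 Hz to a dense per-sample stage score map, and a segment classifier
aggregates that map over windows of i samples into a T × K
row-stochastic posterior.  Because the classifier is a mean-pool
followed by two pointwise convolutions, its weights are independent of
i: the label frequency is an inference-time argument ranging from one
label per 30 s (i = 3840) to one label per sample (i = 1, 7680
labels/min).

Assumptions: stages are describable from any standard EEG and EOG
derivation (no EMG or other modalities); stage-relevant structure
survives resampling to 128 Hz; a single channel pair suffices, with
robustness obtained by training on randomly drawn pairs and by
majority-voting predictions over all pairs at inference.

## Architecture

* Encoder: `depth` (default 12) blocks of conv(k=9, s=1, zero-padded
  "same") → ELU → batch-norm → max-pool(k=2, s=2).  Filters start at
  `base_filters` (default 5) and grow by c ← ⌊c·√2⌋ per block
  ([5, 7, 9, 12, 16, 22, 31, 43, 60, 84, 118, 166] at the defaults).
* Bottleneck (flag, default on): one further conv–ELU–batch-norm block
  at the deepest resolution with ⌊166·√2⌋ = 234 filters, standard
  U-Net practice.
* Decoder: mirrored blocks — nearest-neighbour ×2 upsampling, conv(k=2),
  ELU, batch-norm, concatenation with the encoder skip taken after that
  block's batch-norm (before pooling), then conv(k=9) → ELU →
  batch-norm; filters shrink on the reversed √2 schedule.  A pointwise
  convolution projects the final feature map to K = 5 channels (the
  high-frequency score map).
* Segment classifier: per-channel mean-pool (kernel i, stride i), a
  pointwise convolution with ELU (hidden width K by default), a second
  pointwise convolution, softmax over stages.

Numerical/structural choices where the design was open: the decoder
merge convolution mirrors the encoder kernel (9); convolutions preserve
length via zero padding; the ELU → batch-norm ordering follows the
encoder block description and is kept uniform; odd-length feature maps
are right-padded by edge replication before pooling and cropped back
after upsampling, so any input whose length is a multiple of i is
accepted (inputs of at least 2^depth = 4096 samples are recommended so
the bottleneck sees a non-degenerate signal).  Argmax ties anywhere in
the pipeline resolve to the lowest stage index — deterministic, and
measure-zero for real network outputs.

The theoretical receptive field is computed by the standard
RF ← RF + (k − 1)·jump recursion over the conv/pool stack up to the
deepest convolution; the default configuration spans ≈ 9.1 min of
128 Hz signal, consistent with a model that can consult minutes of
context on both sides of an epoch.  `count_parameters` gives the
closed-form trainable-scalar count (convolution weights/biases plus
batch-norm scale/shift) and is tested against brute-force enumeration
of the constructed tensors; the default build has ≈ 1.9 M parameters.

The engine (convolution, ELU, batch normalization, pooling, upsampling,
segment pooling, fused softmax/cross-entropy, Adam) is written directly
on float32 numpy arrays with hand-derived backward passes.  The test
suite validates every backward pass by central finite differences with
the engine switched to float64 (relative error below 10⁻⁵ on randomly
probed parameters and on the input gradient), alongside
masking-invariance and bitwise-reproducibility checks.

## Preprocessing

Channels are resampled to 128 Hz by polyphase filtering with a rational
rate approximation accurate to ≤ 10⁻⁶ relative error; each channel is
then standardized over the whole recording to median 0 / IQR 1, and
scaled values are clipped at ±20 (i.e. 20 IQRs from the median).  A
flat channel (IQR 0) is centred and left unscaled with a warning.
Signal outside the scored hypnogram is stripped; label i covers the
half-open interval [i·p, (i+1)·p) with p the label period, and trailing
sub-period signal is stripped rather than padded.  R&K stages S3/S4
merge into N3; MOVEMENT, UNKNOWN and any unrecognized annotation map to
a MASK token that is shown to the network but excluded from loss and
metrics.  Channel roles are inferred from free-text EDF labels by
case-insensitive heuristics (EOG/ROC/LOC/E1/E2 → EOG; EEG or 10-20 site
codes → EEG), overridable by an explicit map.

## Training

Batches of 64 windows × 35 epochs (2240 predictions per step) are drawn
through the four-level hierarchy described in `somnoseg.sampling`; the
dataset level uses the convex blend P(D) = α·P₁ + (1−α)·P₂ of uniform
and size-proportional sampling with α = 0.5 — the blend reading is
adopted because a product of the two probabilities would not normalize,
contradicting the stated intent of weighing both policies equally.
Class-balanced placement draws an anchor stage uniformly, redraws up to
five times if the record lacks it, then falls back to uniform placement.
Records shorter than the window are left-aligned, zero-padded and
MASK-padded.  Augmentation replaces, independently per element, a
log-uniform fraction in [0.001, 0.3] of one channel (p = 0.1) and one
entire channel (p = 0.1) with Gaussian noise N(μ̂, 0.01) centred on the
element's mean; labels are untouched.

The loss is unweighted cross-entropy averaged over unmasked positions;
masked positions contribute exactly zero gradient.  The full-scale
optimizer settings (Adam, η = 10⁻⁷, 443 steps per epoch, early stopping
on validation loss with patience 100, no regularization) are the
defaults of `TrainSpec`; they presume a multi-cohort corpus far beyond
what the synthetic generator emulates.  `TrainSpec.desk_scale()`
(batch 8, T = 9, η = 10⁻⁴, 50 steps/epoch, patience 10) sizes training
for minutes-long single-CPU runs, which is the regime every test uses.
One epoch is defined directly by `steps_per_epoch`; validation
monitoring computes a pooled loss and per-dataset mean F1 from each
record's first channel pair.

## Evaluation

Per-record confusion matrices exclude MASK reference positions
entirely.  F1 per stage is 2TP/(2TP+FP+FN); the mean is unweighted over
stages.  A stage present in the reference but never predicted scores 0;
a stage absent from both reference and prediction is excluded from that
record's mean (avoiding 0/0).  "Global" scores pool matrices over
subjects before computing F1; per-subject aggregation reports
mean ± SD.  Channel-pair fusion sums softmax confidences per segment
across all EEG×EOG pairs before the argmax.

## High-frequency analysis

Predictions at 14 frequencies {2, 4, 8, 16, 32, 64, 128, 256, 512, 768,
1280, 1920, 3840, 7680} labels/min (all divisors of the 7680
samples/min internal rate) feed a transition-triplet analysis: the
2/min output fixes the sleep period (first to last non-Wake label);
within each non-overlapping 1.5-h window of that period, labels are
run-length compressed and every consecutive triple (s1, s2, s3) with
s1 ≠ s2 and s2 ≠ s3 — 80 types — increments its slot, with MASK labels
breaking runs.  Counting on the compressed sequence makes the statistic
comparable across frequencies; rates are occurrences per hour; trailing
partial windows are dropped as high-variance.  Leave-one-subject-out
classification fits a 200-tree random forest (Gini impurity, class
weights n/(k·n_c)) whose max_depth, min_samples_leaf and
min_samples_split are drawn from {2..7} and max_features from
{sqrt, log2} — one draw per repetition, reused across that repetition's
folds — with per-subject majority voting over segments and random
tie-breaks; 50 repetitions (protocol default) give a mean ± SD robust
to any single hyperparameter configuration.

## Synthetic data

The generator emulates exactly what the method consumes: multi-cohort
EDF inputs with heterogeneous montages and rates, 30-s Markov-chain
hypnograms started in Wake with MASK epochs injected at a configurable
rate, and stage-conditioned signals (10 Hz wake rhythm, low-amplitude
5 Hz N1, 13 Hz spindle-band N2, high-amplitude 1 Hz N3, low-amplitude
EEG with large 0.35 Hz EOG deflections in REM, high-variance noise
under MASK).  It does **not** emulate real PSG features such as
K-complexes, artifacts with realistic spectra, inter-scorer label
noise, apnea event waveforms or EMG — so passing tests demonstrate that
the pipeline's mechanics and learning dynamics are correct, not that
clinical-grade accuracy is reached on real recordings.  The
two-population cohort (default 25 controls / 55 cases, mirroring the
healthy/OSA contrast) derives the case transition matrix from the
control matrix by multiplying N2/N3/REM → W/N1 probabilities by an
arousal multiplier (default 4) and rebalancing the self-transition;
multiplier 1 reproduces the control population exactly and serves as
the null.

## Problem sizes and limitations

Test and example runs use deliberately small sizes chosen as the
package's desk-scale study conditions: depth-6/4-filter models, 15-min
records, 20-record training sets for the learnability check (≥ 0.95
training mean F1), 8-h hypnograms for the 80-subject classification
experiment, and 2-3 repetitions of the RF protocol where only a
pass/fail separation property is asserted.  Known limitations: the
numpy engine is single-threaded and unsuited to training the full
12-block model on real corpora; EDF writing assumes integer sampling
rates and 1-s records; the exact layer table of the full-scale
published architecture is not reproduced — the body-faithful build's
parameter count and receptive field are treated as consistency notes
only; and consensus-scoring comparison machinery is out of scope (the
metrics accept any reference hypnogram).
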