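# Methods

This note documents the model, the numerical and design choices behind
the implementation, what the synthetic generator does and does not
emulate, and the problem sizes used in the automated experiments.

## Model and assumptions

The classifier is a pure Transformer over channel-pure patches of raw
(preprocessed) EEG.  The assumptions this encodes:

- **Class information lives in band-limited oscillatory structure** that
  a linear projection of 0.256-s patches can expose.  The embedding rows
  act as temporal filters; their spectra are inspectable
  (`inspect.filter_spectra`), with a bin resolution of fs/D =
  3.90625 Hz at the defaults.
- **Spatial structure is learned, not imposed.**  There is no
  convolution over sensors and no fixed sensor graph; the only
  montage-specific parameters are the positional rows keyed by
  (sensor, time slot).  Everything else — embedding, encoder,
  heads — is montage-agnostic, which makes multi-dataset training and
  weight transfer trivial: transfer copies the projection, cls token,
  encoder, and every positional row whose key was seen in pre-training,
  and freshly initializes the rest plus the classification head.
- **Token order carries no information by itself** (self-attention is
  permutation-invariant); the tests assert that permuting channels
  together with their provenance leaves predictions unchanged.

## Preprocessing

8–45 Hz 4th-order Butterworth band-pass applied forward-backward
(zero-phase, so the effective attenuation doubles); polyphase resampling
with T_out = round(T·fs_target/fs); channel-wise z-score with
statistics pooled over all trials of one recording session (population
formula, ddof = 0 — this is a normalization, not an estimate), training
and evaluation sessions normalized separately.  A zero-variance channel
is an error, never silently regularized.  The filter order and phase
policy are not dictated by the approach; zero-phase Butterworth-4 is
standard EEG practice and is what the frequency-response tests pin down.

## Augmentation

Gaussian noise (σ = 0.1), DC shift (σ = 0.1), amplitude scaling
(μ = 1, σ = 0.1) — each drawing **one scalar per trial** applied to all
channels, so the relative channel amplitudes that carry the class
signal are preserved — and time-shifted cropping of a 512-sample
window (8 tokens per channel at D = 64; a two-second nominal window is
500 samples, but only 8·64 = 512 is consistent with eight whole
tokens).  Evaluation always uses the deterministic centered crop.
Sigmas are in z-scored units since augmentation follows normalization.
Channel subsampling for pre-training keeps each channel independently
with probability p (floor of one channel); the keep distribution is a
free choice, Bernoulli being the simplest defensible one.

## Self-supervised objective

Selection operates on **time slots jointly across channels** (one action
per slot shared by all channels at that slot): masking a single sensor
would be trivially interpolable from its spatial neighbors because
referenced EEG signals are close to linear mixtures across the scalp.
Defaults: selection probability 0.3; actions mask/random/keep =
80/10/10.  The mask is a learned d_model vector substituted after
embedding; random replacements are drawn uniformly from the embedded
patches of the current batch.  Keep-action patches enter the loss (the
BERT convention; the alternative is not distinguishable at the level of
the written recipe).  The loss is the cosine distance between the
reconstruction head's output and the original patch, averaged over
manipulated patches only; it is scale-invariant in both arguments and
undefined (an error) for zero-norm patches.

In backpropagation, tokens replaced by the mask vector route their
gradient to the mask token; random-replacement tokens are treated as
constants (no gradient to the source patch's embedding).  This keeps
the batch elements independent in the backward pass; the effect on the
objective is second-order since replacements are rare (3% of slots).

## Optimization

AdamW with β = (0.9, 0.95) and decoupled weight decay 0.01 on matrix
weights (embedding, attention projections, FFN, reconstruction head);
no decay on biases, LN parameters, the positional table, the cls and
mask tokens, or — by default — the classification head.  The head's
decay is raised to 1.0 only for supervised pre-training, where the head
is discarded afterwards and strong shrinkage keeps it from absorbing
dataset idiosyncrasies.  Gradients are clipped at global norm 1 (the
post-clip norm of every step is logged and asserted).  The learning
rate ramps linearly from 0 to 3·10⁻⁴ over the warm-up steps and then
follows a cosine decay to 3·10⁻⁵, stepped per optimizer step with
warmup_steps = warmup_epochs × steps-per-epoch.  An epoch is one pass
over all training trials.

Mixed batches may combine trials with different channel counts; shorter
token sequences are padded, padded keys are masked out of the attention
normalization, padded rows are zeroed, and the losses ignore them, so a
padded batch produces exactly the gradients of its unpadded trials
(asserted to 1e-10).

The whole network and its backward pass are written in NumPy (float64).
Analytic gradients are validated against central finite differences for
both objectives in the test suite.  The LN epsilon is 1e-12: small
enough that layer normalization is exactly invariant (to ~1e-9) under
per-token affine transforms — the property that makes DC-shift and
amplitude-scaling augmentations nearly vacuous for this
architecture — while still guarding degenerate all-constant tokens.

## Interpretability

Filter spectra report the argmax over nonzero DFT bins of each
embedding row (a constant row reports 0 Hz).  Positional similarity
summarizes each sensor by the mean of its per-slot positional rows and
reports pairwise cosine similarity; the per-sensor aggregate is a
choice (the per-patch rows are the actual parameters), and the mean is
the simplest one.  Attention rollout averages heads per layer, corrects
each layer for the residual path as ½(A + I) with rows renormalized,
and multiplies the corrected matrices from first to last layer; the cls
row, reshaped to (channel, slot), is the per-patch importance map.

## Synthetic generator

Each trial is unit-variance 1/f Gaussian background (spectral exponent
1) plus one alpha (8–12 Hz, amplitude 1.0) and one beta (18–26 Hz,
amplitude 0.5) sinusoid per channel at random in-band frequency and
phase, with a log-normal per-subject gain (σ = 0.1).  Class encoding
follows event-related desynchronization: the oscillation amplitudes on
the class's designated motor-cortex channels are multiplied by
(1 − effect_size) — C3 for RIGHT_HAND, C4 for LEFT_HAND, Cz for FEET,
both C3 and C4 for BOTH_HANDS, beta-only at Cz for TONGUE, nothing for
REST.  Defaults mirror common motor-imagery recordings: 4-s trials at
250 Hz (1000 samples), balanced classes.

What it does **not** emulate: volume conduction and sensor
cross-correlation, non-stationary artifacts (blinks, EMG), non-sinusoidal
rhythms, and realistic single-trial SNR.  A pipeline that passes the
end-to-end tests demonstrably recovers lateralized band-power structure
under clean conditions; it does not follow that published accuracies on
recorded data are reproduced, and no test claims that.

## Problem sizes in the automated experiments

The experiments in the test suite are deliberately desk-scale; all are
seeded and bit-reproducible:

- End-to-end learnability: 2 subjects × 60 trials/class × 2 classes,
  3 channels, separate evaluation session; two-block model; 40 epochs.
- Chance-level control: effect size 0, 15 epochs, accuracy required to
  stay within two binomial standard deviations of 0.5.
- Transfer: supervised pre-training (25 epochs, head decay 1.0) on a
  five-channel synthetic corpus, then fine-tuning 30 trials on a
  three-channel montage; epochs-to-threshold compared to from-scratch
  over seeds {1, 2, 3}.
- Ablation grid: 6 augmentation regimes × fractions {10%, 17.5%, 35%,
  70%} of the pool remaining after a fixed, checksummed 30% evaluation
  split; one-block model, 30 epochs, seeds {1, 2, 3}.
- Self-supervised toy: a one-block model memorizes 10 patches to cosine
  loss < 0.05 within 500 steps.

## Known limitations

- No GPU path and no mixed precision; the NumPy implementation is meant
  for desk-scale study, not for pre-training on 40K-trial corpora.
- The positional registry must be populated before the optimizer is
  created; montages cannot grow mid-`fit` (register first, or use
  `transfer_weights`).
- The EDF import adapter is a thin optional wrapper and is not
  exercised by the test suite.
- Checkpoints store the registry key list as JSON inside an `.npz`
  archive; they are versioned with a format tag but not
  forward-compatible across config schema changes.
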