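# Methods

## Overview

`cwtdcnn` classifies 1-second, 35-channel EEG segments as *epileptic* or
*normal* in three stages:

1. **Scalogram imaging.** Each channel is transformed with the continuous
   wavelet transform (CWT) using the real Morlet ("morl") mother wavelet
   ψ(t) = exp(−t²/2)·cos(5t). Coefficient magnitudes are min–max
   normalized per image, mapped through a jet colormap and bilinearly
   resized to a 100×100 RGB tile.
2. **Tiling.** The 35 tiles are concatenated into one 500×700 (H×W)
   composite: channel *i* occupies grid column *i* mod 7 and row ⌊*i*/7⌋
   (7 columns × 5 rows, row-major, origin top-left).
3. **Classification.** A lightweight depthwise CNN maps the composite to a
   single sigmoid probability of the epilepsy class (encoded 1; normal is
   0, so sensitivity is the epilepsy-class recall).

A synthetic EEG generator with spike-and-wave class structure makes the
entire chain trainable and testable without clinical data.

## Continuous wavelet transform

The implementation discretizes

    W(a, b) = (1/√a) · Σₙ x[n] · ψ((n − b)/a),   b = 0 … T−1

at unit sample spacing over integer scales a = 1…100 (one scale per pixel
row of the tile before resizing). The sum is truncated at the signal
boundary — samples outside the record contribute nothing — which is
algebraically identical to a full linear convolution with the sampled
wavelet; the code evaluates it by FFT convolution and the test suite checks
equality with the direct sum to < 1e−8 (measured below 1e−12 relative L2).
Because the wavelet is real, no conjugation is involved, and magnitude
|W| is rendered (the conventional scalogram). The scale carrying a
sinusoid of frequency f at rate fs is a* ≈ fc·fs/f with fc ≈ 0.8125.

Signals are demeaned per channel before the transform: a DC offset carries
no rhythm information and only produces boundary artifacts; this also makes
a constant signal render as the exact zero image. Per-image min–max
normalization (no dataset-level normalization) makes rendering invariant to
amplitude scaling, so the pipeline is robust to unknown amplitude units.

The jet colormap is defined in closed form — channel value =
255·clamp(1.5 − |4v − κ|, 0, 1) with κ = 3, 2, 1 for R, G, B — rather than
any plotting library's lookup table, so image bytes are reproducible
bit-for-bit across environments. Colormapping happens at full precision
before the bilinear resize; quantization to 8 bits is the final step.
Bilinear resizing uses half-pixel-centre sampling with independent axis
stretching.

## Network

Layer stack (input: any RGB image, internally resized):

| # | layer | kernel | output (150×210 input) | params |
|---|-------|--------|------------------------|--------|
| 1 | resize + rescale to [0,1] | – | 150×210×3 | 0 |
| 2 | conv2d, 4 filters, relu | 3×3 | 148×208×4 | 112 |
| 3 | depthwise, relu | 5×5 | 144×204×4 | 104 |
| 4 | conv2d, 8 filters, relu | 3×3 | 142×202×8 | 296 |
| 5 | maxpool, stride 2 | 2×2 | 71×101×8 | 0 |
| 6 | depthwise, relu | 5×5 | 67×97×8 | 208 |
| 7 | maxpool, stride 2 | 2×2 | 33×48×8 | 0 |
| 8 | flatten | – | 12 672 | 0 |
| 9 | dropout 0.6 | – | 12 672 | 0 |
| 10 | dense 512, relu | – | 512 | 6 488 576 |
| 11 | dense 1, sigmoid | – | 1 | 513 |

Total: 6 489 809 trainable parameters. Convolutions use valid padding and
stride 1; pooling floors odd dimensions; depthwise layers have channel
multiplier 1 (no pointwise convolution follows — the depthwise layers are
used bare, which is what makes the network light). These conventions are
forced by the output-shape column: any other padding/stride choice breaks
the arithmetic. The resize target is configurable (50×70, 100×140,
150×210, 200×280 in the studied grid).

The runtime engine is a NumPy implementation with explicit forward and
backward passes (im2col + GEMM convolutions, argmax-scatter pooling,
inverted dropout, fused sigmoid + binary cross-entropy head for numeric
stability). Its correctness is pinned by (a) numeric gradient checks of
every parameter against central finite differences in float64, (b)
agreement of its tensor shapes and parameter totals with the independent
analytic calculator over randomized architectures. Weights use He-normal
initialization for relu layers and Glorot-uniform for the sigmoid head;
training arithmetic is float32.

### Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7), learning rate 2e−4, batch size 128,
binary cross-entropy, up to 100 epochs; RMSprop (ρ = 0.9) is the supported
alternative. The default split is segment-level: a uniform permutation with
the first ⌈0.75·N⌉ records as training data and the remaining 25% used for
both validation and test. Segment-level splitting of per-subject data can
leak subject identity between partitions, so a subject-level mode (whole
subjects assigned to one side, ≥ 2 subjects per class) is provided; the
segment mode remains the default because it is the protocol the reported
results correspond to. Decision threshold 0.5, with p ≥ threshold counted
as epilepsy. Dropout and shuffling draw from substreams of one seed;
repeated runs with the same seed are bit-identical.

## Synthetic EEG generator

The generator emulates the *structure* of a two-class clinical screening
dataset, not its physiology:

- **Background (both classes):** per-channel 1/f^β noise (β = 1, spectral
  synthesis with random phases) plus one alpha-band sinusoid (8–13 Hz,
  random frequency and phase, amplitude 1.5× the noise RMS), zero-mean.
- **Spatial mixing:** per subject, a fixed random 35×35 mixing matrix with
  unit diagonal and off-diagonal rows scaled to absolute sum 0.5 (strictly
  diagonally dominant, hence full rank) correlates the channels, so
  subject-wise splitting is meaningful.
- **Epileptiform activity:** a 3 Hz spike-and-wave train — Gaussian spike
  (σ = 10 ms) followed by an opposite-polarity half-sine slow wave
  (180 ms, 0.6× spike height) — injected synchronously into a per-subject
  focal subset of ⌈0.5·35⌉ = 18 channels at 4× each channel's background
  RMS. Foci are fixed per subject because an epileptic focus is
  subject-level anatomy; the focal (rather than global) injection is what
  makes the 35-tile composite informative instead of redundant.
- **Composition:** 40 subjects per class by default, each contributing a
  uniform-random 10–20 segments of 1 s at fs = 500 Hz (T = 500). Variable
  per-subject counts mirror real acquisition; the per-subject volume is
  kept at a size appropriate for a synthetic verification study rather
  than a clinical archive. fs = 500 Hz is a choice — clinical EEG spans
  roughly 250–1000 Hz and 500 gives a clinically plausible bandwidth.

Randomness is counter-based (`SeedSequence([seed, class, subject,
segment])`), so any subset of the dataset is bit-identical to the
corresponding slice of the full dataset.

**What passing tests do and do not show.** The synthetic classes differ by
a strong, spectrally localized, focal signature; a linear classifier on two
bandpower features already separates them (verified ≥ 85% held-out
accuracy). End-to-end success therefore demonstrates that the imaging,
tiling, training and evaluation machinery is correct and that the CNN can
exploit localized time-frequency structure — it says nothing about
performance on real EEG, where class differences are subtler, artifacts
abound, and inter-subject variability dominates.

## Evaluation

Confusion counts with epilepsy positive, and the five scores accuracy,
sensitivity (= recall), specificity, precision and F1 (harmonic mean of
precision and sensitivity). A score whose denominator is zero is reported
as 0 with a warning rather than NaN so parameter sweeps never crash.
Scores are fractions internally and ×100 at two decimals in reports.

## Numerical choices and edge cases

- CWT boundary: truncated summation (≡ zero padding), no reflection.
- Degenerate normalization: a magnitude field whose span is ≤ 1e−9 of its
  maximum renders as the zero image (absorbs FFT roundoff on analytically
  zero coefficients).
- Colormap inputs outside [0, 1] are clamped with a warning.
- Maxpool ties resolve to the first maximum (argmax order); pool windows
  never overlap and trailing rows/columns are dropped.
- The image-rendering CWT path runs in float32 (outputs are quantized to
  8 bits); the analysis path (`cwt`) is float64.
- Checkpoints store the architecture and raw weight arrays; evaluation of
  a loaded checkpoint is bit-identical to the in-memory model.

## Problem sizes

The standard verification experiment used by the tests and the acceptance
script is 40 subjects/class × 10–20 segments (≈ 1200 segments), 75/25
segment split, 100×140 network input, 15 epochs — chosen as the smallest
configuration that exercises every stage at full fidelity while training
comfortably on a single CPU. The 150×210 default input and 100-epoch
default budget remain available for larger runs.

## Known limitations

- No artifact modelling (EMG/EOG), no ictal/interictal distinction, no
  montage or re-referencing support.
- The NumPy engine is single-threaded and CPU-bound; it is sized for the
  verification study, not for large-scale training.
- EDF import reads the first 35 signals and first full second only, and
  carries no labels.
- `sklearn.utils.estimator_checks` is not fully applicable: the estimators
  operate on 3-D signal / 4-D image batches rather than 2-D feature
  matrices.
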