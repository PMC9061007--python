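# Methods

## Problem and model

The package classifies a subject as **symptomatic** (has experienced a TIA
or ischemic stroke; positive class, label 1) or **asymptomatic** from four
grayscale B-mode ultrasound plaque ROIs: the largest plaque of each carotid
artery imaged in the transverse and the longitudinal plane (views LT, LL,
RT, RL). The ROIs have arbitrary pixel sizes — transverse ROIs are roughly
square, longitudinal ROIs elongated — and are never padded or resized.

The classifier is a four-path convolutional network. Each path is

1. a **feature-extraction backbone**: the VGG16 convolutional stage (five
   blocks of 3×3/stride-1/pad-1 convolutions + ReLU, 2×2/stride-2 max pool
   after each block *except the last*), mapping an H×W view to k feature
   maps of size ⌊H/16⌋×⌊W/16⌋ (k = 512 at full width);
2. an **object-specific pooling module** producing a fixed-length vector:
   * transverse paths (1, 3): spatial pyramid pooling over grid levels
     1×1 + 2×2 + 3×3 = **14 bins** per channel → a 14k-vector;
   * longitudinal paths (2, 4): multilevel strip pooling over full-width
     strip levels 1 + 2 + 3 = **6 strips** per channel → a 6k-vector.

The four descriptors are concatenated (2·14k + 2·6k = 40k; 20 480 at
k = 512) and classified by fully connected layers (4096, 4096, 2) with
dropout before the last layer. Pooled bin boundaries use the adaptive
convention bin *i* of *n* over extent *e* = [⌊i·e/n⌋, ⌈(i+1)·e/n⌉), which
tiles every cell and may overlap by one cell when *e* is not a multiple of
*n*.

Because the network is written as an explicit-backprop numpy engine
(`osfpnet.nn`), every layer has a hand-derived gradient; the test suite
verifies the full model's gradients against central finite differences.

## Choices the architecture description leaves open

* **Pooling operators.** Max for SPP (the classical pyramid-pooling
  choice), average for MSP (the classical strip-pooling choice). Both are
  configurable.
* **Strip orientation.** MSP level (a, 1) means a divisions along the
  *height*, each spanning the full width, so each strip aggregates
  long-range horizontal context of the elongated longitudinal plaque. The
  opposite orientation is representable by supplying explicit levels.
* **FE weight sharing.** The four backbones share the architecture but hold
  independent weights (distinct seeds); `tie_fe_weights=True` shares one
  set across the paths.
* **Dropout.** Drop probability 0.5 (the canonical value), realized as
  inverted dropout: training multiplies by a Bernoulli(keep) mask scaled by
  1/keep, so inference is the exact identity.
* **Head width.** The full-width head keeps the VGG16 sizes (4096, 4096, 2)
  even though the concatenated input is 20 480-dimensional; the tiny
  variant uses (256, 256, 2).
* **Pretrained weights.** `BackboneConfig(pretrained=True)` loads a
  user-supplied `.npz` export of the 13 ILSVRC-trained VGG16 conv layers
  (`pretrained_weights=...`), replicates grayscale input to 3 channels and
  applies the usual per-channel normalization. No checkpoint is bundled;
  without one the package trains from a seeded He initialization on
  1-channel input.
* **Normalization.** 8-bit intensities are divided by 255 at model input;
  no mean subtraction unless pretrained weights demand it.

## Training and cross-validation protocol

Cross-entropy loss; SGD with momentum 0.9; initial learning rate 1e-3
reduced ×10 after every 6 epochs (lr(e) = 1e-3 / 10^⌊e/6⌋); 30 epochs;
batch size exactly 1 (heterogeneous input sizes make larger dense batches
impossible, and gradient accumulation is deliberately not used). "Epoch"
here means one pass over the training subjects.

Cross-validation is 5-fold at **patient level** (the K5 protocol, ~80/20).
Subset sizes are drawn with a seeded generator uniformly from [65, 70]
until they sum to n for the 333-subject reference size — e.g. seeds
reproduce partitions like 66/66/66/66/69, so holding out a 66-subject fold
trains on 267 subjects — and the range is scaled proportionally
(⌊65n/333⌋ to ⌈70n/333⌉) for other cohort sizes, falling back to a
near-equal split with a warning if infeasible. Augmentation, when enabled,
is applied to the training split only, *after* fold assignment; a leakage
guard compares base patient identities (augmentation tags stripped) every
round and hard-stops on overlap.

Per-fold test predictions use the **final-epoch** model by default.
`selection='best'` restores the epoch with the highest held-out accuracy —
kept available because the protocol reports a "best model", but flagged
optimistic since there is no nested validation split; it is never used for
the no-signal null check below, where maximizing over epochs would bias
accuracy above chance.

## Augmentation

The ×7 recipe: original + uniform rescales by 0.8, 0.9, 1.1, 1.2 (bilinear,
output dims rounded) + horizontal and vertical flips. One transform is
applied consistently to all four views of a subject and the label is kept,
so 333 subjects / 1332 images become 2331 variants / 9324 images. A scale
that would push any view below the 48-px minimum input side is a validation
error naming the subject.

## Synthetic cohort

Clinical data being unavailable, the generator emulates its structure: per
subject, four views with per-image sizes drawn uniformly (transverse sides
64–160 px with W/H kept inside [0.78, 1.30], a margin within the
near-square band [0.75, 1.33] so that ±1 px rounding under the 0.8–1.2×
augmentation scales cannot leave it; longitudinal heights 64–96 px with
aspect 2.5–5). The 64-px minima guarantee that every augmentation scale
stays above the backbone's 48-px minimum. Labels are balanced 117:216
(symptomatic fraction 0.35) by default, mirroring the reference cohort's
imbalance.

Texture is multiplicative speckle: I = clip(B·R, 0, 255) with R unit-mean
Rayleigh (fully developed speckle, contrast ≈ 0.52) and B a constant
echogenicity level plus Gaussian-smoothed (σ = 8 px) low-frequency
heterogeneity. Class effect per unit `effect_size`: symptomatic mean level
135 → 135 − 12·effect; heterogeneity amplitude 8 → 8·(1 + 1.5·effect).
Since multiplicative speckle ties absolute variance to brightness, the
heterogeneity effect is expressed in the *relative* local variation
(coefficient of variation), which is higher for the symptomatic class;
`effect_size=0` makes the classes exactly exchangeable.

What this emulates — and does not: the generator reproduces geometry,
speckle statistics, class imbalance and a controllable class-separable
texture; it does not simulate beamforming, attenuation, anatomy, or the
actual (unknown) intensity statistics of symptomatic vs. asymptomatic
plaques, whose direction here is an assumption motivated by the clinical
association of hypoechoic/heterogeneous plaques with risk. Passing
end-to-end tests therefore demonstrates that the pipeline can learn a
texture signal of this kind at these sample sizes — not clinical-grade
accuracy.

## Problem sizes used in tests

The package's own desk-scale study conditions: the end-to-end sanity runs
use the tiny-width configuration (width_scale = 0.125, k = 64, head
256/256/2) on 40-subject cohorts with compact ROIs (transverse 48–64 px,
longitudinal 48–60 px high, aspect 2.5–3.2). The separable-cohort run uses
`effect_size = 2.0`, the full 30-epoch schedule and three seeds with a
majority-pass criterion (from-scratch batch-1 training occasionally
collapses for an unlucky init — an honest property of the recipe). The
no-signal null check uses `effect_size = 0`, 10 epochs, and requires the
pooled 5-fold test accuracy to stay within 3σ (binomial SE at n = 40) of
the majority-class chance rate.

## Numerical notes

* float32 weights/activations by default; float64 available (used by the
  gradient-check tests). Cross-entropy is computed in float64 via a
  max-shifted softmax.
* He-normal initialization, zero biases, seeded `numpy.random.default_rng`
  everywhere; training, cohort generation and fold assignment are
  bit-reproducible given their seeds.
* 2×2 max pooling drops an odd trailing row/column (floor semantics), so
  spatial extent after the four pools is exactly ⌊·/16⌋; the minimum input
  side is 48 px = 3·2⁴, the smallest size whose final map supports the 3×3
  pyramid level.
* Metrics with zero denominators are reported as `None` with an
  `undefined` flag, never as 0, and fold means skip undefined entries.
* Degenerate paired t-tests (zero-variance differences) are flagged rather
  than returning a spurious p-value.

## Known limitations

* No GPU path and no conv-algorithm tricks (im2col only): full-width
  (k = 512) training is impractical on CPU; the tiny variant is the
  supported desk-scale configuration.
* Checkpoints store weights + config echo in `.npz`; loading a
  `pretrained=True` configuration re-requires the original weights file.
* The one-path and fixed-size four-path baseline configurations exist only
  as config degenerations, not as maintained models.
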