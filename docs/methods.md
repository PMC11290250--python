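# Methods

## Problem and model

The package classifies grayscale transcranial-sonography (TCS) midbrain
images into *normal* and *abnormal* (Parkinson's disease), where the
imaging marker is substantia-nigra hyperechogenicity: an abnormally bright
patch inside the darker, butterfly-shaped midbrain. The classifier is a
residual convolutional network with three additions aimed at this signal:

1. **MVGGC input stage.** Each image `X` in [0,1] is expanded into three
   gamma views `C·((X+ε)/C)^γ` with `γ ∈ {1, 1/2.2, 2.2}`, `C = 1`,
   `ε = 1e-6`, stacked as input channels. `γ < 1` stretches the dark range,
   `γ > 1` the bright range, so the first convolution sees the hyperechoic
   signal at three contrast settings. ε gives the transform a finite slope
   at zero during backpropagation through preprocessing-free inputs; at
   1e-6 it changes values by < 1e-5 gray levels.
2. **ADCP.** After the 7×7/2 stem, an ASPP-style pyramid of 3×3 dilated
   convolutions at rates 6/12/18 plus a global-pooling branch (GAP → 1×1
   conv → BN → ReLU → broadcast) is concatenated and re-weighted by CBAM:
   a channel gate `σ(MLP(avgpool) + MLP(maxpool))` with a shared
   bottleneck MLP (reduction ratio 16, hidden width `max(1, C//r)`), then
   a spatial gate `σ(conv7×7([avg_c; max_c]))`. A 1×1 fusion convolution
   with stride 2 reduces channels and takes over the downsampling role of
   the stem max-pool, which makes the module a drop-in replacement for it
   in ablations. BN + ReLU follow every branch conv and the fusion conv,
   conventional ASPP practice.
3. **SE residual blocks.** Each two-3×3-conv basic block is recalibrated
   before the residual addition: `SQ = GAP(F)`,
   `EX = σ(W2·ReLU(W1·SQ))`, output `EX ⊙ F + shortcut`. Reduction 16.
   The gate acts after the second convolution's batch norm, before the
   shortcut add, the standard SE-ResNet placement.

Depth 34 (`[3,4,6,3]` basic blocks) is the reference configuration;
depth 18 (`[2,2,2,2]`) is the scaled-down variant used throughout the test
suite. The three additions are independent on/off flags, so all eight
ablation variants are constructible from one config: flag off substitutes
single-view input, a 3×3/2 max-pool, or a plain basic block respectively.

The printed attention composition applies the spatial gate to the
channel-gated map (standard CBAM); the excitation nonlinearity is the
sigmoid. Both sub-gates are strictly inside (0,1), so attention only
attenuates activations — this is asserted as a property test.

## Numerical core

The network, its reverse-mode gradients, and AdamW are implemented in
NumPy (`amsnet.nn`): convolution via patch unfolding with stride, padding
and dilation; batch norm with running statistics; explicit backward passes
for every attention gate including the argmax routing of max-pooled
descriptors. Decoupled weight decay (0.01) applies to rank-≥2 tensors
only. Everything is float64 and single-threaded-deterministic: identical
seeds give bit-identical loss traces, which the suite asserts. Correctness
is established against nested-loop scalar oracles (convolution, both
attention gates, SE, the residual block) and a central-difference gradient
check through the full miniature network at 1e-4 relative tolerance
(parameters whose gradient magnitude sits below the finite-difference
noise floor, ~1e-7, are excluded from comparison).

Initialization: He-normal for convolutions and linear layers, zeros for
biases, BN gamma 1 / beta 0, all drawn from one seeded generator per model.

## Data pipeline

Cohort accounting follows the clinical protocol the package models: per
class, train gets `floor(0.6·N)` and the remainder splits evenly between
validation and test (odd remainder to validation). For a 675/434 cohort
this gives 405/135/135 and 260/87/87; with fivefold training augmentation
the training set becomes 2025 + 1300 = 3325 images while validation and
test stay at 222 each. "Fivefold" means the original plus four augmented
copies; copies carry the provenance id of their source and only training
images are augmented, so augmentation cannot leak across splits.

Augmentation defaults: horizontal flip p = 0.5, rotation ±15°, Gaussian
blur σ ∈ [0.1, 2], rescale ∈ [0.9, 1.1]; rotation and rescale are bilinear
with reflect boundaries so augmented corners carry no constant-padding
class cue. Resizing is pure bilinear with corner-aligned sampling
(`i·(H−1)/(side−1)`): constants are preserved exactly and a linear ramp
survives an upsample/downsample round trip to float precision. For the
severe 448 → 64 reduction used in scaled-down experiments, a Gaussian
prefilter at σ = factor/2 precedes the bilinear resize
(`downsample_antialiased`); without it the speckle aliases into
class-irrelevant high-variance texture that measurably slows
generalization at small sample sizes.

## Training protocol

Class-weighted cross-entropy (weights `N/(K·N_class)` by default), AdamW
with lr 1e-4, betas 0.9/0.999, weight decay 0.01, batch size 4. The
learning rate halves after 5 consecutive epochs without a relative
train-loss improvement of 1e-4 and never increases. Training runs at least
`min_epochs` (50 by default) and stops once the train loss has not
improved for 10 epochs beyond that point. The retained checkpoint is the
epoch with the highest validation accuracy (ties to the earlier epoch),
including that epoch's batch-norm running statistics, so re-evaluating a
reloaded checkpoint reproduces the recorded accuracy exactly.

## Synthetic phantom

The generator emulates only what the classification task needs: a
parenchyma background at 0.5 mean intensity, a hypoechoic butterfly
(two ellipses of semi-axes 110×60 px at ±25°, laterally offset, interior
at 0.45× background), and for abnormal images one hyperechoic patch
(additive brightness 0.3, radius uniform in 12–32 px, center uniform over
positions keeping the patch inside the butterfly, smooth rim of
max(2, 0.2·r) px). Multiplicative speckle is a gamma field with shape 8
(mean 1, sd ≈ 0.35), lightly smoothed (σ = 1 px) to give it spatial grain,
renormalized to mean 1; the product is clipped to [0, 1]. Images are
rendered at 448×448 and downsampled by the pipeline, so the resize stage
is exercised. Lesion placement randoms come from a stream separate from
the texture stream, so setting the lesion brightness to zero makes the
abnormal generator bit-identical to the normal one — the degenerate-case
contract in the tests.

What it does *not* model: acoustic shadowing and the temporal-window
geometry, depth-dependent attenuation and focus, anatomical variability of
the midbrain outline (the geometry is fixed; only the lesion varies), and
annotation overlays. Passing tests therefore demonstrate that the
implementation learns and evaluates correctly on a task with the right
gross structure, not that the architecture reaches clinical accuracy on
real TCS data.

The phantom's design target, asserted in the suite, is that a trivial
classifier — thresholding the mean of the top-1% brightest pixels inside
the midbrain mask — separates the default-parameter classes with > 0.9
accuracy on 200 samples. The learning task is thus demonstrably solvable,
which is what makes the training-convergence tests meaningful.

## Scaled-down study sizes

The suite and the acceptance script train a depth-18 network with stage
widths (8, 16, 32, 64) on 200 phantoms downsampled (anti-aliased) to
64×64, split 6:2:2, for at most 50 epochs with the reference optimizer
settings — sizes chosen once so the NumPy implementation trains in
minutes on one CPU core. Dataset-accounting checks run at the full
675/434 cohort size on count level and on miniature images.

## Known limitations

- Parameter counts depend on unstated branch widths of the original
  architecture; `count_parameters` reports the count for any config but no
  particular printed total is asserted.
- Batch-norm statistics with batch size 4 are noisy; the best-epoch
  checkpoint criterion partially compensates.
- The NumPy core is CPU-only and float64; it is sized for the scaled-down
  experiments, not for 224×224 training at the full cohort size.
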