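# Methods

## Problem and model

`weedseg` implements a lightweight convolutional encoder–decoder for
per-pixel semantic segmentation of field imagery into three classes —
soil/paddy background, crop and weed — aimed at the compute envelope of
embedded weeding-robot hardware (~0.11 M parameters, ~0.24 G operations per
256×256 frame).

The backbone is a six-stage U-shaped network with channel plan
{8, 16, 24, 32, 48, 64}. Stage 1 is a conv block (3×3 convolution + batch
norm + GELU) at full resolution; each deeper encoder stage halves the
resolution with 2×2 max pooling and widens the channels with a conv block,
or in stages 4–6 with the refinement dilated conv block. The decoder
mirrors the ladder: at each step a conv block narrows the channels at the
coarse resolution, bilinear interpolation doubles the resolution, and the
matching encoder output is added element-wise (addition, never
concatenation, keeps the skip path parameter-free). A bare 3×3 convolution
maps the final 8 channels to class logits; softmax is applied only at
inference and in the loss.

Three bespoke blocks augment the baseline:

* **Dual attention (DA)**, inserted at the top of encoder stages 2–6
  (before the pooling, at the incoming resolution and channel count C).
  Branch 1 is external attention: the pointwise-projected, group-normalised
  input is scored against a learnable key memory `M_K ∈ R^{4C×C}`, softmax
  over the 4C memory slots turns each pixel into a convex combination of
  the value memory `M_V ∈ R^{4C×C}`'s rows, and a second pointwise
  projection maps back. Because the memories are learned across the whole
  dataset rather than derived from the sample, the branch is linear in
  pixel count and acts as a regulariser on small datasets. Branch 2 is a
  channel gate: global average pool → a single 3-tap 1-D convolution shared
  by all channels → sigmoid → per-channel rescaling. The block output is
  `GELU(branch1 + branch2 + x)`.
* **Refinement dilated conv (RDC)** replaces the channel-widening conv
  block in encoder stages 4–6. The input is split into four channel
  groups; group k is filtered depthwise (one 3×3 kernel per channel) at
  dilation rate (1, 2, 5, 8)[k] with padding equal to the rate, covering
  local detail through wide context in parallel; a pointwise convolution
  re-fuses the concatenated groups to the stage's output width. Depthwise
  branches plus a pointwise fuse cost far fewer parameters than the dense
  3×3 they replace.
* **Spatial connectivity attention (SCA)** gates every skip connection with
  a single shared kernel: per stage, the channel-wise max map and mean map
  (2 channels) are convolved by one 7×7 dilation-3 kernel (padding 9), a
  sigmoid turns the response into a gate in (0, 1), and the skip becomes
  `gate·x + x`. Weight sharing across all six stages fixes the block at
  2·7·7 + 1 = 99 scalars regardless of depth.

Ablation variants (`U_VI`, `U_VI+RDC`, `U_VI+DA`, `U_VI+SCA`,
`U_VI+RDC+DA`, `full`) toggle these blocks and are constructed by name via
`build_variant`.

## Matrix order and normalisation choices in DA

The attention product is evaluated as `Softmax(X₁) ⊗ M_V` with
`X₁ = proj(X) ⊗ M_Kᵀ ∈ R^{N×4C}`; this is the only dimensionally valid
composition of the two memories. The softmax is taken over the memory
dimension (size 4C), so each pixel's attention weights form a convex
combination of memory rows (asserted to 1e-6 in the tests). The
external-attention "double normalisation" (softmax over pixels followed by
an ℓ1 over slots) is a known alternative; it is not implemented by default.

## Bias and affine placement

Complexity is part of this model family's contract, so the placement of
bias vectors and norm affines is fixed rather than left to framework
defaults:

* conv blocks use affine batch norm (eps 1e-5, momentum 0.1); encoder conv
  blocks keep a conv bias, decoder conv blocks and the logit head carry
  none;
* norms inside DA and RDC are affine-free group normalisation (4 groups,
  eps 1e-5); each of these blocks instead owns one learnable per-channel
  shift applied after normalisation (its only bias), so the shift is fully
  effective rather than partially absorbed by the norm;
* the DA channel-gate convolution is bias-free (3 scalars); the SCA kernel
  carries a scalar bias.

Under exactly this configuration the six variants count 107 248 / 64 888 /
149 631 / 107 347 / 107 271 / 107 370 trainable scalars — the published
complexity figures for this family (0.1072–0.1074 M at 4 d.p.). Biases
sitting under a training-mode batch norm are redundant directions (batch
centering removes a uniform shift); the gradient-completeness check is
therefore run with inference-mode normalisation, where every parameter
receives a non-zero gradient.

## Operation counting

The profiler reports one multiply-accumulate as one FLOP and applies a
fixed cost table: conv/matmul MACs; batch norm 2 ops/element; max pooling
1 op/output element; global average pooling 1 op/input element; the
inference class-softmax 1 op/logit; group norm, GELU, sigmoid, bias adds,
interpolation and elementwise arithmetic are free. The table was calibrated
so that the counts reproduce the published complexity figures for this
model family (baseline 0.1219 G, full network 0.2445 G ≈ 0.24 G at
256×256); the same calibration fixes two architecture ambiguities — DA
runs before pooling at the incoming resolution, and decoder conv blocks
run before (not after) their upsampling step. The published
operation count for the RDC-only variant is not reproducible under any
cost table consistent with its published parameter count (the two imply
structurally different blocks); the parameter count, being
convention-free, was taken as authoritative, and our RDC variant profiles
at 0.1111 G.

## Loss

`L = 0.8·L_Dice + 0.2·L_CE` on softmaxed logits. Dice pools each class's
soft overlap over all B·H·W pixels — `1 − 2Σpg/(Σp² + Σg² + s)` with
smooth `s = 1e-6` guarding absent classes — then averages over classes;
class-mean keeps the term in [0, 1] at any batch size, so the fixed 0.8/0.2
mix is scale-stable. CE is the pixel-mean negative log-probability of the
true class, computed through log-softmax. Both terms vanish exactly on a
perfect one-hot prediction (up to smooth/clamp), and the compound is the
stated affine combination for any weights (property-tested).

## Metrics

One-vs-rest confusion counts (TP/FP/FN/TN) per class are summed over the
entire image set before any ratio is formed, matching evaluations that
report dataset-total pixel counts. Precision, recall, IOU, F1 and the
class-mean MIOU follow the standard formulas; the identity
`IOU = F1/(2 − F1)` is exact on counts and asserted to 1e-9. Zero
denominators: a class absent from truth and prediction scores 1 (vacuously
perfect); otherwise a metric with a zero denominator scores 0. Predictions
produced at the network resolution are upsampled nearest-neighbour to the
mask's native resolution before counting. Reported values round half-up to
4 d.p.

## Training protocol

AdamW (β = 0.9/0.999, eps 1e-8, decoupled weight decay), lr 0.001, weight
decay 0.01, batch size 6, 150 epochs, per-epoch cosine annealing
`lr(e) = lr₀/2·(1 + cos(πe/E))` with floor 0, and a checkpoint every 5
epochs plus last/best-validation copies — these defaults mirror the
reference recipe; the test-suite runs shrink epochs and canvas size, never
the recipe's structure. Inputs are resized to 256×256 (bilinear for
images, nearest for masks) and standardised per channel with training-split
statistics (fallback mean = sd = 0.5). Augmentation: joint horizontal/
vertical flips and image-only Gaussian blur (probability 0.5, sigma
U[0.1, 2.0] — the blur parameters are this package's choice). Elastic
distortion and shear ("miscut") ops are provided for offline dataset
expansion but sit outside the default path. Checkpoints serialise every
parameter and buffer plus the architecture config; round trips are
bit-exact.

## Synthetic scenes

The generator emulates the structure of the field datasets this model
family targets: a textured brown-soil or green-blue paddy-water background
(optionally with blurred plant reflections that keep the background
label), a few large lobed-rosette crops, and many small thin-stroke weeds,
with a configurable probability of weeds overlapping crops. Rendered
pixels and mask labels coincide exactly, identical seeds reproduce scenes
bit for bit, and dataset splits draw from disjoint seed streams with any
augmentation applied strictly within a split. Default conditions: 256×256
canvas, 3 crops (radius 24–40 px), 12 weeds (radius 4–10 px), overlap
probability 0.3, noise 0.04; radii scale proportionally for smaller
canvases (`SceneSpec.for_size`). What the scenes do *not* emulate —
photometric diversity, real leaf texture, occlusion geometry, class
imbalance at field scale — bounds what desk-scale tests show: they verify
that the implementation can fit and segment structured scenes, not that it
reaches any particular accuracy on real fields.

## Numerical and engine choices

The network runs on a compact numpy reverse-mode autodiff engine
(float64 throughout): convolution (im2col), pooling and bilinear
interpolation are primitives with hand-derived adjoints, everything else is
composed. Each primitive is validated against central finite differences
(tolerance 1e-5 or tighter), and each bespoke block against an independent
dense-loop evaluation of its defining equations. Max pooling splits
gradients equally on ties; bilinear upsampling uses half-pixel alignment;
initialisation is fan-based uniform for convolutions and zero-mean normal
with sd 1/√C for the attention memories. Everything is seeded and
single-threaded-deterministic.

## Desk-scale validation sizes

Benchmark-scale training (hundreds of real images, 150 epochs at 256×256)
is out of scope; the suite instead validates at desk scale: block oracles
on grids ≤ 4×4, the overfit smoke run on 8 synthetic 64×64 scenes with at
most 500 optimiser steps (it reaches MIOU > 0.9 in well under that), and
complexity checks by structural counting. `scripts/acceptance.py` re-runs
these from scratch.

## Known limitations

* Training throughput is modest (numpy, float64); the package is built for
  correctness and desk-scale experiments, not production training runs.
* The published operation count of the RDC-only variant cannot be
  reconciled with its published parameter count (see "Operation counting").
* Metrics assume single-label masks; no ignore-label or boundary-tolerance
  support.
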