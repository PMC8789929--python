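# Methods

This note documents the models, numerical choices, and design decisions
behind `deephips`, and what the synthetic test surface does and does not
demonstrate.

## Overlap losses

All losses operate on per-voxel class probabilities `p_ci` (rows sum to
one) against one-hot targets `t_ci`, with the background counted as a
class. Five objectives share one interface (`losses.get_loss`):

| name | form | class weights |
|------|------|---------------|
| `cce` | mean voxelwise cross-entropy | none |
| `dl`  | per-class-mean soft Dice | none |
| `gdl` | pooled Dice | `w_c = 1/V_c²` |
| `jl`  | per-class-mean soft Jaccard | none |
| `gjl` | pooled Jaccard | `w_c = 1/V_c` |

where `V_c = Σ_i t_ci` is the class volume. Numerical choices:

* A smoothing constant `ε = 1e-5` is added to every ratio denominator, so
  absent classes never divide by zero. Its effect on reported values is
  below `1e-4` for the problem sizes used anywhere in the package.
* Classes with `V_c = 0` receive weight 0 and are dropped from both sums
  of the generalized losses (with a logged warning). The quadratic GDL
  weighting is the variant known to become unstable on small or absent
  classes; the weight clamp keeps it finite without hiding that
  instability.
* Probabilities are clipped to `[1e-7, 1 − 1e-7]` before logarithms
  (`cce` only).
* A widely circulated printed form of the Jaccard loss places the `1/NC`
  factor outside a single pooled ratio; that form evaluates to `1 − 1/NC`
  even on a perfect prediction and therefore cannot serve as a
  vanishing-at-optimum objective. The package implements the
  per-class-mean reading (structurally parallel to the Dice loss) as the
  default and keeps the pooled-ratio form available via
  `jaccard_loss(..., literal=True)` for comparison.
* Whether the cross-entropy comparison arm should carry class weights is
  an open choice; it is implemented unweighted, the common default.

With deep supervision, the configured loss is evaluated at the low,
medium, and high resolution outputs and combined as
`0.1·low + 0.2·medium + 0.7·high` (configurable).

## Network

`NetworkSpec` describes a 3-D U-Net with `levels` resolution stages
(defaults: 2 input channels, 4 stages, 64 base filters doubling per
stage, 3 convolution blocks per stage, NC = 4 classes). Each block is
Conv3³ (stride 1, shape-preserving zero padding, He-initialized, with
bias) → BatchNorm → ReLU. Downsampling is 2× max pooling; upsampling is
parameter-free repetition; encoder features are concatenated into the
matching decoder stage; one dropout layer (rate 0.5) closes each encoder
stage. With `deep_supervision` the graph carries three softmax outputs —
at the bottleneck, at the deepest decoder stage, and at full resolution —
and concatenates the upsampled coarse probabilities into the input of the
decoder stages named by `feedback_levels` (default: the full-resolution
stage). The auxiliary heads are BN + 1×1×1 convolution; the final head is
a plain 1×1×1 convolution. `deep_supervision=False` yields the classic
single-head U-Net used as the ablation comparator.

**Calibration of the default wiring.** The reference parameter total of
35,085,580 pins the architecture far more tightly than a prose
description can: block ordering, which stages carry heads, and where the
feedback enters all leave the graph underdetermined, and the most obvious
construction — BN-first blocks, heads at the three finest decoder stages,
feedback into the two finest — misses that total by ~0.03% no matter how
the upsampling operator, head kernel, or class count is chosen. An
exhaustive audit over block order, bias placement, downsampling and
upsampling operators, head placement/kernels, and feedback wiring found
exactly one structurally complete configuration reproducing the figure:
the one frozen as the default above (Conv→BN→ReLU blocks, heads at
bottleneck / deepest decoder stage / full resolution with BN on the two
auxiliary heads, a single probability feedback into the full-resolution
stage). The per-layer audit (`deephips audit`, `DSUNet3D.summary()`)
exposes every layer's contribution so the accounting can be re-derived
independently; the audit counts 57 conv/BN layers (layer-count
conventions vary, so this number is reported, not asserted).

The trainable count comprises convolution kernels and biases plus the
normalization scale/shift parameters; BN running statistics are
non-trainable state. BN uses ε = 1e-3 and running-average momentum 0.99.

## Inference and TTBN

`predict` runs the graph in evaluation mode (running BN statistics,
dropout off). With `mode="ttbn"` the BN layers instead use the presented
sample's own statistics, computed per call over the single sample (the
training protocol uses batch size one); dropout stays off and the stored
statistics are never modified. Per-sample statistics exactly cancel any
global affine intensity change *after* the first normalization layer;
with the default conv-first blocks the zero padding at crop borders
breaks exactness, so the robustness claim is tested behaviorally (Dice
under intensity scale-shift) rather than as an identity. Whether dropout
should also stay active in this mode is an open choice; it is disabled
here because stochastic test-time segmentations are rarely acceptable.

## Augmentation

* **Flip pooling**: left crops are mirrored along the left-right axis so
  a single right-oriented model trains on both hemispheres (25 bilateral
  subjects → 50 crops; 5 → 10).
* **Smooth/sharpen**: with equal probability Gaussian smoothing
  (σ ∈ [0.3, 1.2] voxels) or unsharp masking (amount ∈ [0.2, 1.0],
  fixed σ = 1), the same operation applied to both channels. The ranges
  are unstated in the protocol being emulated; these defaults span mildly
  degraded to mildly oversharpened image quality and are exposed in the
  config.
* **mixup**: convex combinations with λ ~ Beta(0.3, 0.3), applied to
  images and one-hot labels alike, producing valid soft label fields.
  Partners are drawn within the dataset. Each augmentation applies per
  sample with probability 0.5 (configurable).

Training: Adam with default parameters (lr 1e-3, β = 0.9/0.999,
ε = 1e-7), batch size one, 200 epochs by default, constant learning rate,
best-validation-loss checkpoint retained (falling back to best training
loss without validation data). Coarse-scale supervision targets are
majority-vote downsampled label maps (ties break to the lowest label
index), which keeps every target a valid one-hot field; under mixup the
soft targets are average-pooled instead. All randomness derives from one
seed; two runs with equal seeds produce identical histories.

## Evaluation

Dice per structure, unweighted mean over structures (background
excluded), and whole-structure Dice on the union of all foreground
labels. Empty-vs-empty masks score 1 (both raters agree the structure is
absent); empty-vs-nonempty scores 0. K-fold planning is a seeded shuffle
followed by a contiguous partition; each fold holds out
`max(2, round(n_train/8))` validation cases, which reproduces the 5-of-40
and 2-of-8 splits of the bilateral 25- and 5-subject cohorts. Evaluation
happens in the template space of the crops; no back-projection to native
space is attempted.

## Phantom generator

The phantom emulates what makes subfield segmentation geometrically hard:
a curved tube (arc span 150°, arc radius 10 voxels, tube radius 7 voxels,
with a small left-right drift making crops genuinely chiral) partitioned
into nested laminar shells at 45% / 75% / 100% of the tube radius. The
three-label protocol uses the shells directly; the five-label protocol
splits the middle shell into three along-arc sectors. Channels are
per-label constant means (T1-like ascending, T2-like descending, ranges
spanning roughly 0.15–0.95), multiplied by a smooth random bias field
(±20%) and degraded with Gaussian noise (sd 0.05 — a
contrast-to-noise ratio of 3–4 between adjacent laminae, comparable to
good high-resolution MRI; Rician noise optional). `degrade` provides
controlled corruptions (exact scale-shift, blur, extra noise) for
robustness experiments.

What the phantom does **not** emulate: anatomical shape variability,
partial-volume mixtures at interfaces, anisotropic acquisition,
registration error, or inter-rater label noise. Passing the synthetic
end-to-end checks therefore demonstrates that the losses, network,
optimizer, and inference modes are implemented correctly and can learn
thin curved structures — not that real-data accuracy levels are
reproduced.

## Problem sizes used by the test suite

The end-to-end checks run a levels-3, 8-filter network on 32×24×32
phantoms (tube radius 5, arc radius 7 — the default geometry scaled to
the smaller grid): 20 training phantoms, 300 optimizer steps, 5 held-out
phantoms for the learning check and 10 seeded scale-shifted phantoms for
the TTBN comparison; the ablation harness uses 16³ phantoms with a
4-filter network. These sizes keep the whole suite within minutes on one
CPU while exercising every code path of the full-size configuration;
the full-size network itself is built (and audited) but not trained in
the tests.

## Known limitations

* The numpy autodiff core is single-sample and CPU-bound; it is meant
  for correctness and small-scale study, not for training the full-size
  network on real crops.
* External preprocessing (SANLM denoising, N4, ANTs affine registration,
  LASR super-resolution) is invoked through command hooks, not
  reimplemented; phantoms bypass those steps.
* Training-library expansion with automatically segmented extra cases is
  supported only as an ingest path for externally produced label maps.
* Repeat upsampling (rather than transposed convolution) was fixed by the
  parameter audit; alternative operators would change the parameter
  count.
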