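# Methods

## Problem setting

Semantic segmentation of 3-D medical volumes acquired in several
co-registered modalities — the motivating case is multi-sequence brain MR
(T1, T1c, T2, FLAIR) with glioma compartment labels (0 background,
1 necrosis, 2 edema, 3 non-enhancing tumor, 4 enhancing tumor). Different
tissue classes are conspicuous in different sequences (edema in T2/FLAIR,
enhancing tumor in contrast-enhanced T1), so the central design question is
*how* to fuse modality information inside an encoder–decoder network.
This package implements and compares five fusion designs, the last of which
— softmax modality attention — is the method of interest.

## Modality-attention fusion

Given per-modality feature maps U_m ∈ R^(W×H×D×C), m = 1..M, at one
resolution level:

1. sum fusion: U = Σ_m U_m;
2. channel descriptor by 3-D global average pooling:
   z_c = (1 / WHD) Σ_ijk U_c(i,j,k);
3. one fully-connected layer per modality produces digits
   z^m = A_m z + b_m ∈ R^C, all guided by the shared descriptor z;
4. a per-channel softmax across modalities,
   w_c^m = exp(z_c^m) / Σ_m exp(z_c^m)  (so Σ_m w_c^m = 1),
   followed by the convex recombination Ũ = Σ_m w^m ⊙ U_m.

Properties used as test invariants: the weights form a probability vector
per channel; Ũ lies voxelwise in the convex hull of the modality features;
the block is the identity at M = 1; weights are invariant to a common shift
of all digits; permuting modalities (together with their generators)
permutes weights and leaves Ũ unchanged.

Design choices where the design was genuinely open:

* **Digit generators are full-rank C→C affine maps** with bias, no
  bottleneck; an optional `fusion_reduction` flag inserts a shared
  reduction layer (selective-kernel style) but defaults to off — the plain
  reading of "M full-connection layers".
* **The shared descriptor z is computed from the summed map** and fed to
  all M generators; this is the only reading under which a single z guides
  M digit vectors.
* **Zero initialisation of the digit generators.** With no normalisation
  layers in the network, the descriptor z is O(10); random full-rank maps
  then produce digits large enough to saturate the per-channel softmax at
  0/1 immediately, freezing the attention at its random initial preference.
  Zero-started generators open the block at exactly uniform weights 1/M
  (plain averaged fusion) and let training break the symmetry; this is the
  standard zero-init-the-gate practice for attention/residual branches.
  All other parameters are Kaiming-initialised.
* Softmax is computed with per-channel max subtraction (mathematically the
  identity; required numerically).
* **Fusion is applied at every encoder resolution level and at the
  bottleneck**, producing the fused skip features a single decoder
  consumes; per-level blocks have independent parameters.

The single-path baseline attention is a squeeze-and-excitation gate
(GAP → FC(C→C/r) → ReLU → FC(C/r→C) → sigmoid, multiplicative per channel),
default reduction r = 2 at the small desk-scale widths.

## Networks

Encoder: one input 3-D convolution (3³) followed by `levels` down-sampling
stages — a stride-2 convolution (7³ by default; the kernel sizes are config
fields because the conventional residual-network order is the transpose,
7³ input / 3³ down) and one residual block (two 3³ convolutions + identity
shortcut) per stage, ReLU throughout, no normalisation layers. Channels
double per stage from `base_channels` (desk default 8; a paper-scale
network would use 64). Height and width halve per stage and must divide by
2^levels; depth halves only while ≥ 2, so a 16-slice patch runs
16 → 8 → 4 → 2 → 1 through four stages.

Decoder: per level, a 3³ transpose convolution (the exact adjoint of the
down-sampling geometry, output size pinned to the skip shape), channel
concatenation with the fused skip, one 3³ convolution + ReLU; finally a
1×1×1 convolution and voxelwise softmax over K classes. Argmax ties break
to the lowest class index.

Variants: `single_concat` (modalities as input channels), `multi_unshared`
(one encoder per modality), `multi_shared` (one parameter set, M passes,
element-wise-sum skip fusion), `multi_shared_attention` (the same but with
the attention block at every level — the only delta, so ablations isolate
the fusion mechanism), `single_se` (single path with SE gates after each
convolution block).

All of this runs on a small in-package reverse-mode autodiff engine over
numpy (float32): im2col convolution, adjoint transpose convolution via
stride dilation, broadcasting arithmetic, softmax, concat. Gradients of
every operator are finite-difference tested.

## Training

SGD with momentum 0.9, weight decay 5e-4, batch size 1, up to 400
iterations, cross-entropy plus soft Dice loss (unweighted sum). The soft
Dice term averages (2Σp_k t_k + s)/(Σp_k + Σt_k + s) over foreground
classes, unsquared, s = 1e-5; probabilities are clamped by 1e-7 inside the
CE log. The default learning rate is 1e-3; the printed source value
("10e-3") literally equals 1e-2, and the desk-scale experiment presets use
1e-2, which on these small networks converges in ~100 steps without
instability. No LR schedule, no augmentation. Patches are random
`patch_depth`-slice windows of preprocessed cases, sampled uniformly with a
seeded generator; training is bit-deterministic for a fixed seed on a fixed
BLAS, and checkpoints carry parameters, momentum buffers and the sampler
state so a resumed run reproduces the uninterrupted loss trace exactly.

## Preprocessing

Fixed order crop → resize → normalize: tight bounding box of voxels nonzero
in any modality (recorded for inverse mapping); per-slice bilinear resize of
each axial plane to `target_axial` (nearest neighbour for labels — the only
vocabulary-preserving choice); per-modality z-score (x − μ)/(σ + eps),
eps = 1e-6. Whether normalisation statistics should exclude background
zeros is exposed as `normalize_scope` (default whole-volume) rather than
guessed. Inference tiles the depth axis into `patch_depth` windows
(zero-padded tail, pad recorded), averages class probabilities where
windows overlap, and strips the pad on reassembly.

## Evaluation

Predictions are binarised into the printed region groupings WT {1,2,3,4},
TC {1,3,4}, ET {4} and scored with Dice = 2TP/(2TP+FP+FN),
Sensitivity = TP/(TP+FN), PPV = TP/(TP+FP). When a region is empty in both
prediction and truth, all three metrics are 1.0 by documented convention
(needed for cases that legitimately lack a region, e.g. no enhancing
tumor). Note the TC grouping follows the printed label set even though
label 1 is necrosis in the stated vocabulary; the set, not the prose, is
implemented. Tables report per-case means (pooled-voxel aggregation is
available via the metric primitives). `mean_foreground_dice` averages
per-class Dice over classes present in truth or prediction, so empty
classes do not inflate it.

## Synthetic phantoms

The generator reproduces exactly the two properties the pipeline depends
on: nested tumor compartments and modality-specific contrast. Lesions are
concentric ellipsoids (class 1 outermost … class K−1 innermost, shells
shrinking linearly; random anisotropy 0.7–1.3; in-plane centers keep
lesions inside the field of view, while the shallow slice axis may truncate
them as a real imaging stack does). Voxel intensity in modality m is
contrast[k, m] plus additive Gaussian noise. Defaults — 48×48 plane,
16 slices, M = 2, K = 3, background 20, dim 45, bright 110, σ = 10 —
give a class separation (≈ 6σ) comparable to conspicuous lesions in
skull-stripped MR. What the phantoms deliberately lack: bias fields, Rician
noise statistics, partial-volume effects, anatomy, inter-subject
variability. Passing the learning tests therefore shows the pipeline trains
and the attention mechanism behaves as designed — not that clinical-grade
accuracy transfers to real data.

Two contrast presets define the experimental conditions: `brats_like`
(class k bright in modality k−1, dim elsewhere — every modality is
informative about a designated class) and `single_modality` (all class
contrast in one modality, the others flat background + noise — the
asymmetric condition for attention-recovery and ablation runs).

## Desk-scale experiment sizes

The acceptance experiments run on one CPU in minutes; sizes are the
package's own desk-scale conditions:

* end-to-end learning: 20 training / 5 held-out phantoms (16×48×48, M=2,
  K=3, σ=10), attention variant, base 8 channels, 2 levels, 3³ kernels,
  lr 1e-2, 120 iterations;
* attention recovery: 5 seeds, 4 training phantoms (8×24×24), asymmetric
  contrast, base 4 channels, 1 level, 150 iterations; the channel-mean
  bottleneck weight of the informative modality is compared to the noise
  modality's;
* directional ablation: 5 matched seeds, 8 training / 4 test phantoms
  (8×32×32, σ=15, asymmetric), shared-sum vs attention fusion, 60
  iterations each.

## Known limitations

* No normalisation layers (none are specified for the reference design);
  at larger widths/depths this limits trainable learning rates.
* Transpose-conv output sizes are pinned to skip shapes, so the decoder
  only supports the encoder's own geometry.
* The engine is single-threaded numpy; paper-scale training (155×240×240
  BRATS volumes, 64 base channels, GPU hours) is out of scope, and the
  printed benchmark Dice values of the reference study are correspondingly
  not reproduced here — the harness reproduces the comparison *structure*
  and the directional effect of attention fusion.
* Rician noise, bias fields and augmentation are documented extension
  points, not implemented.
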