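# modseg

Multi-modal 3-D semantic segmentation with **softmax modality-attention
fusion**, for co-registered multi-sequence volumes such as brain MR
(T1, T1c, T2, FLAIR) with glioma compartment labels.

Different MR sequences make different tissue classes conspicuous — edema in
T2/FLAIR, enhancing tumor in contrast-enhanced T1 — so a segmentation
network that consumes several sequences must decide *how much of each
modality to trust, per feature*. This package implements a multi-path 3-D
encoder–decoder family in which each modality runs through a (optionally
parameter-shared) residual encoder, and the per-level skip features are
fused by a learned, channel-wise softmax competition across modalities:

    U   = Σ_m U_m                                     (sum fusion)
    z_c = (1/WHD) Σ_ijk U_c(i,j,k)                    (3-D global avg pool)
    z^m = A_m z + b_m                                 (one FC per modality)
    w_c^m = exp(z_c^m) / Σ_m exp(z_c^m),  Σ_m w_c^m = 1
    Ũ   = Σ_m w^m ⊙ U_m                               (convex recombination)

A single decoder with transpose convolutions, concatenated skips and a
1×1×1 softmax head produces per-voxel class probabilities. Training uses
SGD (momentum 0.9, weight decay 5e-4, batch 1) on cross-entropy + soft
Dice loss; evaluation reports Dice, Sensitivity and Positive Predictive
Value over the standard tumor region groupings WT = {1,2,3,4},
TC = {1,3,4}, ET = {4}.

Five network variants span the fusion design space — modalities as input
channels (`single_concat`), per-modality paths with independent or shared
parameters and element-wise-sum fusion (`multi_unshared`, `multi_shared`),
shared paths with the attention fusion (`multi_shared_attention`), and a
single path with squeeze-and-excitation channel gates (`single_se`) — so
that the attention mechanism is the only delta in ablations.

Everything runs on a small in-package reverse-mode autodiff engine over
numpy (im2col 3-D convolutions, adjoint transpose convolutions, SGD with
momentum, Kaiming init), so the package has no deep-learning framework
dependency and trains desk-scale networks on one CPU in minutes. A
synthetic phantom generator (nested ellipsoidal lesions with
modality-specific contrast and Gaussian noise) provides fully labelled
multi-modal datasets for testing and experiments; NIfTI and MetaImage I/O
let the same pipeline run on real skull-stripped, co-registered data.

## Worked example

Train the shared-path variant with and without attention fusion on
modality-asymmetric phantoms (all class contrast in modality 0, modality 1
pure noise), matched seeds and budgets:

```python
from modseg import single_modality_contrast
from modseg.training import run_experiment

config = dict(
    seed=7, n_train=8, n_test=4,
    phantom=dict(dims=[8, 32, 32], n_modalities=2, n_classes=3,
                 contrast=single_modality_contrast(3, 2, informative=0).tolist(),
                 noise_sigma=15.0, lesion_radius_range=[4, 10]),
    network=dict(base_channels=8, levels=2, down_kernel=3),
    train=dict(lr=0.01, max_iterations=60, patch=[32, 32, 8]),
    preprocess=dict(target_axial=[32, 32], patch_depth=8),
    variants=["multi_shared", "multi_shared_attention"],
)
results = run_experiment(config)
print(results[["variant", "dice_WT", "dice_TC", "sensitivity_WT", "ppv_WT"]]
      .round(3).to_string(index=False))
```

which prints

```
               variant  dice_WT  dice_TC  sensitivity_WT  ppv_WT
          multi_shared    0.889    0.778           0.841   0.960
multi_shared_attention    0.935    0.772           0.913   0.965
```

Each row is the per-case mean over the 4 held-out phantoms: `dice_WT` is
the whole-tumor overlap (1.0 = perfect), `sensitivity_WT` the fraction of
true tumor voxels recovered, `ppv_WT` the fraction of predicted tumor
voxels that are correct. Under this asymmetric condition the attention
variant recovers more whole tumor than plain sum fusion at the same budget,
because the softmax weights learn to down-weight the pure-noise modality.

A command-line surface wraps the same functions:

```bash
modseg phantom --spec spec.yaml --n 20 --out data/
modseg train --config exp.yaml --cases data/ --out run/
modseg eval --model run/final.npz --config exp.yaml --cases data/ --out metrics.csv
modseg experiment --config sweep.yaml --out results/
```

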