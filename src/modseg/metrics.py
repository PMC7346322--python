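"""Segmentation losses and evaluation metrics with tumor-region grouping.

Evaluation follows the standard brain-tumor protocol: the multi-class
prediction is binarised into three nested regions —

* **WT** (whole tumor):       labels {1, 2, 3, 4}
* **TC** (tumor core):        labels {1, 3, 4}
* **ET** (enhancing tumor):   label {4}

— and each region is scored with Dice = 2TP/(2TP+FP+FN),
Sensitivity = TP/(TP+FN) and Positive Predictive Value = TP/(TP+FP).
When a region is empty in both prediction and truth all three metrics are
1.0 by convention (a low-grade case without enhancing tumor that the model
also leaves empty is a perfect answer, not an undefined one).

Training uses voxel-mean cross-entropy plus a soft Dice loss over the
foreground classes, as an unweighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .autodiff import Tensor

#: Region label sets (printed groupings of the BRATS-2015 vocabulary).
REGIONS: dict[str, frozenset[int]] = {
    "WT": frozenset({1, 2, 3, 4}),
    "TC": frozenset({1, 3, 4}),
    "ET": frozenset({4}),
}

METRIC_NAMES = ("dice", "sensitivity", "ppv")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class LossConfig:
    dice_smooth: float = 1e-5
    log_eps: float = 1e-7            # probability clamp inside log
    class_weights: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be positive")


def region_binarize(labels: np.ndarray, region: str | frozenset[int]) -> np.ndarray:
    """Boolean mask of voxels whose label belongs to the region's label set."""
    label_set = REGIONS[region] if isinstance(region, str) else frozenset(region)
    return np.isin(labels, sorted(label_set))


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    if pred_mask.shape != truth_mask.shape:
        raise ValueError(f"mask shapes differ: {pred_mask.shape} vs "
                         f"{truth_mask.shape}")
    p = pred_mask.astype(bool)
    t = truth_mask.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dice_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:        # both masks empty: perfect agreement by convention
        return 1.0
    return 2.0 * c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    if denom == 0:
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / denom


def ppv(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    if denom == 0:
        return 1.0 if c.fn == 0 else 0.0
    return c.tp / denom


def evaluate_masks(pred_labels: np.ndarray, truth_labels: np.ndarray
                   ) -> pd.DataFrame:
    """3 regions × 3 metrics for one case; rows indexed by region name."""
    if pred_labels.shape != truth_labels.shape:
        raise ValueError("prediction and truth dimensions differ")
    rows = {}
    for name in REGIONS:
        c = confusion(region_binarize(pred_labels, name),
                      region_binarize(truth_labels, name))
        rows[name] = {"dice": dice_score(c), "sensitivity": sensitivity(c),
                      "ppv": ppv(c)}
    return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]


# Back-compat style alias used throughout the training code.
evaluate_case = evaluate_masks


def mean_foreground_dice(pred_labels: np.ndarray, truth_labels: np.ndarray
                         ) -> float:
    """Mean per-class Dice over foreground classes present in truth or
    prediction (classes absent from both contribute nothing rather than a
    conventional 1.0, so the score reflects actual segmentation quality)."""
    classes = sorted(set(np.unique(truth_labels)) | set(np.unique(pred_labels)))
    scores = []
    for cls in classes:
        if cls == 0:
            continue
        c = confusion(pred_labels == cls, truth_labels == cls)
        scores.append(dice_score(c))
    if not scores:
        return 1.0
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Training losses (autodiff)
# ---------------------------------------------------------------------------

def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(D, H, W) integer labels → (1, K, D, H, W) float32 one-hot."""
    eye = np.eye(n_classes, dtype=np.float32)
    return np.ascontiguousarray(eye[labels].transpose(3, 0, 1, 2))[None]


def cross_entropy_loss(probs: Tensor, truth: np.ndarray,
                       config: LossConfig = LossConfig()) -> Tensor:
    """Voxel-mean CE: −mean log p_true, with probability clamping."""
    k = probs.shape[1]
    t = one_hot(truth, k) if truth.ndim == 3 else truth
    picked = (probs * t).sum(axis=1)             # (N, D, H, W)
    return -((picked + config.log_eps).log().mean())


def soft_dice_loss(probs: Tensor, truth: np.ndarray,
                   config: LossConfig = LossConfig()) -> Tensor:
    """1 − mean over foreground classes of the smoothed soft Dice overlap
    (2 Σ p_k t_k + s)/(Σ p_k + Σ t_k + s); background (class 0) excluded,
    terms unsquared."""
    k = probs.shape[1]
    t = one_hot(truth, k) if truth.ndim == 3 else truth
    if probs.shape != t.shape:
        raise ValueError(f"probability shape {probs.shape} != truth {t.shape}")
    s = config.dice_smooth
    terms = []
    for cls in range(1, k):
        p_c = _class_plane(probs, cls)
        t_c = t[:, cls]
        inter = (p_c * t_c).sum()
        denom = p_c.sum() + float(t_c.sum())
        terms.append((inter * 2.0 + s) / (denom + s))
    mean_overlap = terms[0]
    for term in terms[1:]:
        mean_overlap = mean_overlap + term
    return 1.0 - mean_overlap * (1.0 / len(terms))


def _class_plane(probs: Tensor, cls: int) -> Tensor:
    out = Tensor(probs.data[:, cls], parents=(probs,))

    def bwd(g):
        full = np.zeros_like(probs.data)
        full[:, cls] = g
        probs._accumulate(full)
    out._backward = bwd
    return out


def combined_loss(probs: Tensor, truth: np.ndarray,
                  config: LossConfig = LossConfig()) -> Tensor:
    """Cross-entropy plus soft Dice, unweighted."""
    return cross_entropy_loss(probs, truth, config) + \
        soft_dice_loss(probs, truth, config)
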