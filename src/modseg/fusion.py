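"""Softmax modality-attention fusion of per-modality feature maps.

Given per-modality feature maps U_m (one per MR sequence, all of shape
(W, H, D, C) in the mathematical statement; (N, C, D, H, W) in the tensor
layout used here), the fusion proceeds in four steps:

1.  **Sum fusion**   U = Σ_m U_m                       (integrate information)
2.  **3-D GAP**      z_c = mean over all voxels of U_c (channel descriptor)
3.  **Per-modality digits**  z^m = A_m z + b_m, one full-connection layer
    per modality, all guided by the shared descriptor z
4.  **Softmax competition**  w_c^m = exp(z_c^m) / Σ_m exp(z_c^m), so that
    Σ_m w_c^m = 1 per channel, followed by the convex recombination
    Ũ = Σ_m w^m ⊙ U_m  (per-channel broadcast)

The weights form a convex combination per channel, so the fused map lies
voxelwise inside the hull of the modality values, and with M = 1 the block
is the identity. A squeeze-and-excitation (SE) channel gate is provided as
the single-path attention baseline.

Every step exists both as a pure-numpy function (the algebra, testable
against brute-force oracles) and as an autodiff ``Module`` for use inside
networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Linear, Module, Tensor, stack

__all__ = [
    "FeatureStack", "ModalityWeights", "FusionParameters",
    "sum_fuse", "gap3d", "modality_digits", "softmax_weights",
    "weighted_fuse", "modality_attention_fuse",
    "ModalityAttentionFusion", "SEBlock", "se_recalibrate",
]


# ---------------------------------------------------------------------------
# Plain-array data contracts and algebra
# ---------------------------------------------------------------------------

@dataclass
class FeatureStack:
    """M same-shape per-modality feature maps, spatial dims × channels last:
    each array is (W, H, D, C)."""

    features: list[np.ndarray]

    def __post_init__(self):
        if not self.features:
            raise ValueError("at least one modality required")
        shape = self.features[0].shape
        for i, f in enumerate(self.features):
            if f.shape != shape:
                raise ValueError(f"feature map {i} shape {f.shape} != {shape}")
            if not np.all(np.isfinite(f)):
                raise ValueError(f"feature map {i} contains non-finite values")

    @property
    def n_modalities(self) -> int:
        return len(self.features)

    @property
    def n_channels(self) -> int:
        return self.features[0].shape[-1]


@dataclass
class ModalityWeights:
    """Per-modality per-channel attention weights; each channel's weights
    across modalities form a probability vector."""

    w: np.ndarray        # (M, C)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.ndim != 2:
            raise ValueError("weights must be (M, C)")
        if np.any(self.w < -1e-9) or np.any(self.w > 1 + 1e-9):
            raise ValueError("weights must lie in [0, 1]")
        colsum = self.w.sum(axis=0)
        if not np.allclose(colsum, 1.0, atol=1e-6):
            raise ValueError("weights must sum to 1 over modalities per channel")


@dataclass
class FusionParameters:
    """M affine maps R^C → R^C (weight (C, C) acting as z @ A + b)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self):
        if len(self.weights) != len(self.biases):
            raise ValueError("one bias per weight matrix required")
        for a, b in zip(self.weights, self.biases):
            if a.ndim != 2 or a.shape[0] != a.shape[1] or b.shape != (a.shape[0],):
                raise ValueError("each generator must be a square matrix + bias")

    @property
    def n_modalities(self) -> int:
        return len(self.weights)


def sum_fuse(stack: FeatureStack) -> np.ndarray:
    """Element-wise sum over modalities: U = Σ_m U_m."""
    out = np.zeros_like(stack.features[0], dtype=np.float64)
    for f in stack.features:
        out += f
    return out


def gap3d(u: np.ndarray) -> np.ndarray:
    """3-D global average pooling: z_c is the mean of channel c over all
    W·H·D voxels of the fused map (channels-last input)."""
    u = np.asarray(u)
    if u.ndim < 2 or u[..., 0].size == 0:
        raise ValueError("fused map must have nonempty spatial dims × channels")
    return u.reshape(-1, u.shape[-1]).mean(axis=0)


def modality_digits(z: np.ndarray, params: FusionParameters) -> list[np.ndarray]:
    """One full-connection layer per modality applied to the shared channel
    descriptor: z^m = z A_m + b_m."""
    z = np.asarray(z, dtype=np.float64)
    for a in params.weights:
        if a.shape[0] != z.shape[0]:
            raise ValueError(f"descriptor length {z.shape[0]} != generator "
                             f"input dim {a.shape[0]}")
    return [z @ a + b for a, b in zip(params.weights, params.biases)]


def softmax_weights(digits: Sequence[np.ndarray]) -> ModalityWeights:
    """Softmax across modalities, per channel, with max subtraction for
    overflow safety (mathematically the identity)."""
    d = np.asarray(digits, dtype=np.float64)          # (M, C)
    d = d - d.max(axis=0, keepdims=True)
    e = np.exp(d)
    return ModalityWeights(e / e.sum(axis=0, keepdims=True))


def weighted_fuse(stack: FeatureStack, weights: ModalityWeights) -> np.ndarray:
    """Convex recombination Ũ = Σ_m w^m ⊙ U_m with per-channel broadcast."""
    if weights.w.shape != (stack.n_modalities, stack.n_channels):
        raise ValueError(f"weights shape {weights.w.shape} != "
                         f"(M={stack.n_modalities}, C={stack.n_channels})")
    out = np.zeros_like(stack.features[0], dtype=np.float64)
    for f, w in zip(stack.features, weights.w):
        out += f * w          # w broadcasts over the trailing channel axis
    return out


def modality_attention_fuse(stack: FeatureStack, params: FusionParameters
                            ) -> tuple[np.ndarray, ModalityWeights]:
    """The full fusion: sum → GAP → per-modality digits → softmax → convex
    recombination. With M = 1 the weights are identically 1 and Ũ = U_1."""
    if params.n_modalities != stack.n_modalities:
        raise ValueError("one digit generator per modality required")
    u = sum_fuse(stack)
    z = gap3d(u)
    digits = modality_digits(z, params)
    weights = softmax_weights(digits)
    return weighted_fuse(stack, weights), weights


# ---------------------------------------------------------------------------
# Autodiff modules (the versions the networks train)
# ---------------------------------------------------------------------------

class ModalityAttentionFusion(Module):
    """Trainable fusion block over M feature tensors of shape (N, C, D, H, W).

    The most recently computed weights are kept (as numpy, shape (M, C),
    batch-averaged) on ``last_weights`` for inspection and logging.
    """

    def __init__(self, rng: np.random.Generator, n_modalities: int,
                 channels: int, bias: bool = True, reduction: int | None = None):
        self.n_modalities = n_modalities
        self.channels = channels
        # Optional bottleneck (SK-style reduction); plain full-rank C→C maps
        # by default.
        hidden = channels if reduction is None else max(channels // reduction, 1)
        self.reduce = Linear(rng, channels, hidden, bias=bias) if reduction else None
        in_dim = hidden if reduction else channels
        self.generators = [Linear(rng, in_dim, channels, bias=bias)
                           for _ in range(n_modalities)]
        # Zero-start the digit generators: attention opens exactly uniform
        # (1/M, i.e. plain averaged fusion) and learns deviations. Random
        # full-rank init saturates the per-channel softmax immediately —
        # there is no normalisation layer here to keep the descriptor small.
        for g in self.generators:
            g.weight.data[...] = 0.0
            if g.bias is not None:
                g.bias.data[...] = 0.0
        self.last_weights: np.ndarray | None = None

    def __call__(self, features: Sequence[Tensor]) -> Tensor:
        if len(features) != self.n_modalities:
            raise ValueError(f"expected {self.n_modalities} feature maps, "
                             f"got {len(features)}")
        if self.n_modalities == 1:
            self.last_weights = np.ones((1, self.channels))
            return features[0]
        u = features[0]
        for f in features[1:]:
            u = u + f
        z = u.mean(axis=(2, 3, 4))                       # (N, C)
        if self.reduce is not None:
            z = self.reduce(z).relu()
        digits = stack([g(z) for g in self.generators], axis=0)   # (M, N, C)
        w = digits.softmax(axis=0)
        self.last_weights = w.data.mean(axis=1)
        n, c = w.shape[1], w.shape[2]
        fused = None
        for m, f in enumerate(features):
            wm = _slice_modality(w, m).reshape((n, c, 1, 1, 1))
            term = f * wm
            fused = term if fused is None else fused + term
        return fused


def _slice_modality(w: Tensor, m: int) -> Tensor:
    out = Tensor(w.data[m], parents=(w,))

    def bwd(g):
        full = np.zeros_like(w.data)
        full[m] = g
        w._accumulate(full)
    out._backward = bwd
    return out


class SEBlock(Module):
    """Squeeze-and-excitation channel gate: GAP → FC(C→C/r) → ReLU →
    FC(C/r→C) → sigmoid, applied multiplicatively per channel."""

    def __init__(self, rng: np.random.Generator, channels: int, reduction: int = 2):
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError(f"reduction {reduction} >= channels {channels}")
        self.fc1 = Linear(rng, channels, hidden)
        self.fc2 = Linear(rng, hidden, channels)
        self.last_gate: np.ndarray | None = None

    def __call__(self, u: Tensor) -> Tensor:
        z = u.mean(axis=(2, 3, 4))                       # (N, C)
        s = self.fc2(self.fc1(z).relu()).sigmoid()
        self.last_gate = s.data.copy()
        n, c = s.shape
        return u * s.reshape((n, c, 1, 1, 1))


def se_recalibrate(u: np.ndarray, fc1_w: np.ndarray, fc1_b: np.ndarray,
                   fc2_w: np.ndarray, fc2_b: np.ndarray) -> np.ndarray:
    """Pure-numpy SE gate on a channels-last (W, H, D, C) array (reference
    form of SEBlock for algebraic checks): s = σ(W2·relu(W1·z + b1) + b2),
    output s_c · U[..., c]."""
    if fc1_w.shape[0] != u.shape[-1]:
        raise ValueError("fc1 input dim must equal channel count")
    if fc1_w.shape[1] < 1:
        raise ValueError("SE bottleneck collapsed to zero width "
                         "(reduction ratio >= C is invalid)")
    z = gap3d(u)
    h = np.maximum(z @ fc1_w + fc1_b, 0.0)
    s = 1.0 / (1.0 + np.exp(-(h @ fc2_w + fc2_b)))
    return u * s
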