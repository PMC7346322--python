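"""Multi-path 3-D encoder–decoder segmentation networks.

The encoder is a small residual network: one input convolution (3³ by
default) followed by ``levels`` down-sampling stages (7³ stride-2
convolution + one residual block of two 3³ convolutions each, ReLU
throughout). Height and width halve at every stage and must divide
evenly; depth halves only while it is at least 2 (a 16-slice patch runs
16 → 8 → 4 → 2 → 1 under four stages). Channels double per stage from
``base_channels``.

The decoder mirrors the encoder with 3³ transpose convolutions, combines
each up-sampled map with the matching-resolution skip features by channel
concatenation, and ends in a 1×1×1 convolution + voxelwise softmax over
classes.

Five variants cover the fusion design space:

* ``single_concat``      — modalities stacked as input channels, one path;
* ``multi_unshared``     — one encoder path per modality, independent
                           parameters, skip fusion by element-wise sum;
* ``multi_shared``       — one parameter set run once per modality, sum
                           fusion;
* ``multi_shared_attention`` — shared paths with softmax modality-attention
                           fusion at every resolution level (the method this
                           package exists for);
* ``single_se``          — single path with squeeze-and-excitation channel
                           gates after each convolution block (the
                           single-path attention baseline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import (Conv3d, ConvTranspose3d, Module, Tensor, concat)
from .fusion import ModalityAttentionFusion, SEBlock
from .preprocess import (PreprocessConfig, depth_windows, extract_patches,
                         preprocess_case, reassemble_patches, resize_axial,
                         uncrop)
from .volumes import Case, LabelVolume

VARIANTS = ("single_concat", "multi_unshared", "multi_shared",
            "multi_shared_attention", "single_se")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    variant: str = "multi_shared_attention"
    n_modalities: int = 2
    n_classes: int = 3
    base_channels: int = 8
    levels: int = 4
    input_kernel: int = 3       # paper-literal: 3³ input …
    down_kernel: int = 7        # … and 7³ down-sampling; swap for the
                                # conventional ResNet order if preferred
    blocks_per_level: int = 1
    fusion_bias: bool = True
    fusion_reduction: Optional[int] = None
    se_reduction: int = 2
    patch: Optional[tuple[int, int, int]] = None   # (D, H, W), checked at build
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}; "
                                     f"choose from {VARIANTS}")
        if self.levels < 1:
            raise ConfigurationError("levels must be >= 1")
        if self.n_modalities < 1 or self.n_classes < 2:
            raise ConfigurationError("need >= 1 modality and >= 2 classes")
        if self.patch is not None:
            _, h, w = self.patch
            div = 2 ** self.levels
            if h % div or w % div:
                raise ConfigurationError(
                    f"patch plane {h}×{w} not divisible by 2^levels={div}")

    @property
    def channel_schedule(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.levels + 1)]


def _depth_stride(d: int) -> int:
    return 2 if d >= 2 else 1


class ResBlock(Module):
    """Two 3³ convolutions with an identity shortcut, ReLU after each add."""

    def __init__(self, rng, channels: int):
        self.conv1 = Conv3d(rng, channels, channels, 3)
        self.conv2 = Conv3d(rng, channels, channels, 3)

    def __call__(self, x: Tensor) -> Tensor:
        return (self.conv2(self.conv1(x).relu()) + x).relu()


class EncoderPath(Module):
    """One encoder path; emits features at every resolution level
    (index 0 = full resolution after the input layer, index ``levels`` =
    bottleneck)."""

    def __init__(self, rng, config: NetworkConfig, c_in: int,
                 with_se: bool = False):
        ch = config.channel_schedule
        self.input_conv = Conv3d(rng, c_in, ch[0], config.input_kernel)
        self.down_convs = []
        self.blocks = []
        self.se_blocks = [] if with_se else None
        if with_se:
            self.input_se = SEBlock(rng, ch[0], config.se_reduction)
        else:
            self.input_se = None
        for lvl in range(config.levels):
            rng_ = rng
            self.down_convs.append(
                Conv3d(rng_, ch[lvl], ch[lvl + 1], config.down_kernel, stride=2))
            self.blocks.append([ResBlock(rng_, ch[lvl + 1])
                                for _ in range(config.blocks_per_level)])
            if with_se:
                self.se_blocks.append(SEBlock(rng_, ch[lvl + 1],
                                              config.se_reduction))

    def __call__(self, x: Tensor) -> list[Tensor]:
        f = self.input_conv(x).relu()
        if self.input_se is not None:
            f = self.input_se(f)
        feats = [f]
        for lvl, down in enumerate(self.down_convs):
            sd = _depth_stride(feats[-1].shape[2])
            f = down_forward(down, feats[-1], sd).relu()
            for block in self.blocks[lvl]:
                f = block(f)
            if self.se_blocks is not None:
                f = self.se_blocks[lvl](f)
            feats.append(f)
        return feats


def down_forward(conv: Conv3d, x: Tensor, depth_stride: int) -> Tensor:
    """Apply a down-sampling conv with depth stride decided by the current
    depth (halve while >= 2, keep at 1 otherwise)."""
    from .autodiff import conv3d
    stride = (depth_stride, 2, 2)
    return conv3d(x, conv.weight, conv.bias, stride, conv.pad)


class Decoder(Module):
    """Transpose-conv up-sampling with concatenated skips and a 1×1×1 head."""

    def __init__(self, rng, config: NetworkConfig):
        ch = config.channel_schedule
        self.ups = []
        self.convs = []
        self.se_blocks = [] if config.variant == "single_se" else None
        for lvl in range(config.levels, 0, -1):
            self.ups.append(ConvTranspose3d(rng, ch[lvl], ch[lvl - 1], 3, stride=2))
            self.convs.append(Conv3d(rng, 2 * ch[lvl - 1], ch[lvl - 1], 3))
            if self.se_blocks is not None:
                self.se_blocks.append(SEBlock(rng, ch[lvl - 1], config.se_reduction))
        self.head = Conv3d(rng, ch[0], config.n_classes, 1)

    def __call__(self, skips: Sequence[Tensor]) -> Tensor:
        """``skips``: fused features per level, index 0 full-res …
        index ``levels`` bottleneck. Returns logits (N, K, D, H, W)."""
        from .autodiff import conv_transpose3d
        x = skips[-1]
        for i, lvl in enumerate(range(len(skips) - 1, 0, -1)):
            target = skips[lvl - 1].shape[2:]
            sd = 2 if target[0] != x.shape[2] else 1
            up = self.ups[i]
            x = conv_transpose3d(x, up.weight, up.bias, (sd, 2, 2), up.pad,
                                 target).relu()
            x = concat([x, skips[lvl - 1]], axis=1)
            x = self.convs[i](x).relu()
            if self.se_blocks is not None:
                x = self.se_blocks[i](x)
        return self.head(x)


class SegmentationModel(Module):
    """Full network: encoder path(s) + per-level fusion + decoder."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        m, v = config.n_modalities, config.variant
        self.fusions = None
        if v == "single_concat":
            self.paths = [EncoderPath(rng, config, c_in=m)]
        elif v == "single_se":
            self.paths = [EncoderPath(rng, config, c_in=m, with_se=True)]
        elif v == "multi_unshared":
            self.paths = [EncoderPath(rng, config, c_in=1) for _ in range(m)]
        elif v in ("multi_shared", "multi_shared_attention"):
            shared = EncoderPath(rng, config, c_in=1)
            self.paths = [shared] * m          # the same object: one parameter set
        if v == "multi_shared_attention":
            self.fusions = [ModalityAttentionFusion(
                rng, m, c, bias=config.fusion_bias,
                reduction=config.fusion_reduction)
                for c in config.channel_schedule]
        self.decoder = Decoder(rng, config)

    # -- forward ----------------------------------------------------------
    def forward(self, x) -> tuple[Tensor, Tensor]:
        """x: (N, M, D, H, W) array or Tensor → (probabilities, logits)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[1] != self.config.n_modalities:
            raise ValueError(f"input has {x.shape[1]} modalities, model "
                             f"expects {self.config.n_modalities}")
        v = self.config.variant
        if v in ("single_concat", "single_se"):
            skips = self.paths[0](x)
        else:
            per_path = [path(_modality_plane(x, m))
                        for m, path in enumerate(self.paths)]
            skips = []
            for lvl in range(self.config.levels + 1):
                feats = [pf[lvl] for pf in per_path]
                if self.fusions is not None:
                    skips.append(self.fusions[lvl](feats))
                else:
                    fused = feats[0]
                    for f in feats[1:]:
                        fused = fused + f
                    skips.append(fused)
        logits = self.decoder(skips)
        probs = logits.softmax(axis=1)
        return probs, logits

    __call__ = forward

    @property
    def bottleneck_attention(self) -> Optional[np.ndarray]:
        """(M, C) modality-attention weights of the deepest fusion block from
        the most recent forward pass (attention variant only)."""
        if self.fusions is None:
            return None
        return self.fusions[-1].last_weights


def _modality_plane(x: Tensor, m: int) -> Tensor:
    out = Tensor(x.data[:, m:m + 1], parents=(x,))

    def bwd(g):
        full = np.zeros_like(x.data)
        full[:, m:m + 1] = g
        x._accumulate(full)
    out._backward = bwd
    return out


def build_model(config: NetworkConfig) -> SegmentationModel:
    """Seeded construction; same config → bitwise-identical parameters."""
    return SegmentationModel(config)


# ---------------------------------------------------------------------------
# Whole-case inference
# ---------------------------------------------------------------------------

def predict_case(model: SegmentationModel, case: Case,
                 pre_config: PreprocessConfig,
                 to_original_dims: bool = True) -> LabelVolume:
    """Preprocess, run depth windows through the network, reassemble, argmax.

    The prediction is mapped back to the case's original grid (inverse
    nearest-neighbour resize + placement into the crop box) unless
    ``to_original_dims`` is False, in which case it stays in preprocessed
    space. Argmax ties break to the lowest class index.
    """
    if case.volume.n_modalities != model.config.n_modalities:
        raise ValueError(f"case has {case.volume.n_modalities} modalities, "
                         f"model expects {model.config.n_modalities}")
    images, _, box = preprocess_case(case, pre_config)
    depth = images.shape[1]
    patches = extract_patches(images, None, pre_config.patch_depth)
    probs, ranges = [], []
    for patch in patches:
        p, _ = model.forward(patch["images"][None])
        probs.append(p.data[0])
        ranges.append(patch["range"])
    full = reassemble_patches(probs, ranges, depth)
    pred = np.argmax(full, axis=0).astype(np.int16)
    if not to_original_dims:
        return LabelVolume(pred, frozenset(range(model.config.n_classes)))
    crop_dims = tuple(b - a for a, b in zip(box.start, box.stop))
    pred = resize_axial(pred, crop_dims[1:], kind="label")
    pred = uncrop(pred, box, fill=0)
    return LabelVolume(pred, frozenset(range(model.config.n_classes)))
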