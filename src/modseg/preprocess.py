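"""Volume preprocessing: ROI crop, axial resize, z-scoring, depth patching.

The pipeline order is fixed as crop → resize → normalize. The crop removes
the all-zero margins that surround a skull-stripped head so the network
never trains on empty space; each axial plane is then resampled to a fixed
in-plane size (144×144 by default); finally each modality is z-scored.
Training and inference consume fixed-depth windows of axial slices
(16 by default), with the tail window zero-padded and the pad length
recorded so whole-volume predictions can be reassembled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .volumes import Case, LabelVolume, MultiModalVolume


class EmptyROIError(ValueError):
    """The union of modalities has no nonzero voxel to crop to."""


class CoverageError(ValueError):
    """Patch ranges do not tile the volume depth."""


@dataclass(frozen=True)
class PreprocessConfig:
    target_axial: tuple[int, int] = (144, 144)     # (rows, cols) per axial plane
    patch_depth: int = 16
    normalize_scope: str = "whole_volume"          # or "nonzero_only"
    eps: float = 1e-6

    def __post_init__(self):
        if self.patch_depth < 1:
            raise ValueError("patch_depth must be >= 1")
        if min(self.target_axial) < 8:
            raise ValueError("target_axial must be >= (8, 8)")
        if self.normalize_scope not in ("whole_volume", "nonzero_only"):
            raise ValueError(f"unknown normalize_scope {self.normalize_scope!r}")


@dataclass(frozen=True)
class CropBox:
    """Recorded tight bounding box (half-open slices per axis)."""
    start: tuple[int, int, int]
    stop: tuple[int, int, int]
    original_dims: tuple[int, int, int]

    @property
    def slices(self):
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))


def crop_roi(volume: MultiModalVolume, truth: Optional[LabelVolume] = None
             ) -> tuple[MultiModalVolume, Optional[LabelVolume], CropBox]:
    """Crop all modalities (and truth) to the tight bounding box of voxels
    nonzero in ANY modality; the box is recorded for inverse mapping."""
    mask = np.zeros(volume.shape, dtype=bool)
    for img in volume.images:
        mask |= img != 0
    if not mask.any():
        raise EmptyROIError("volume is identically zero in every modality")
    start, stop = [], []
    for axis in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        nz = np.nonzero(proj)[0]
        start.append(int(nz[0]))
        stop.append(int(nz[-1]) + 1)
    box = CropBox(tuple(start), tuple(stop), volume.shape)
    sl = box.slices
    cropped = MultiModalVolume(list(volume.modality_names),
                               [np.ascontiguousarray(img[sl]) for img in volume.images],
                               volume.spacing)
    ctruth = None
    if truth is not None:
        ctruth = LabelVolume(np.ascontiguousarray(truth.labels[sl]),
                             truth.label_vocabulary)
    return cropped, ctruth, box


def uncrop(grid: np.ndarray, box: CropBox, fill=0) -> np.ndarray:
    """Place a cropped-space grid back into the original dimensions."""
    out = np.full(box.original_dims, fill, dtype=grid.dtype)
    out[box.slices] = grid
    return out


def resize_axial(grid: np.ndarray, target_axial: tuple[int, int],
                 kind: str = "image") -> np.ndarray:
    """Resample every axial (H, W) plane to ``target_axial``; depth untouched.

    Images use bilinear interpolation; labels use nearest neighbour, which is
    the only vocabulary-preserving choice.
    """
    if grid.ndim != 3:
        raise ValueError("grid must be 3-D (D, H, W)")
    if kind not in ("image", "label"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "label" and not np.issubdtype(grid.dtype, np.integer):
        raise TypeError("label resize requires an integer grid")
    out_shape = (grid.shape[0], int(target_axial[0]), int(target_axial[1]))
    if out_shape == grid.shape:
        return grid.copy()
    order = 1 if kind == "image" else 0
    out = _sk_resize(grid, out_shape, order=order, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(grid.dtype if kind == "label" else np.float32)


def zscore_normalize(grid: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Per-modality z-score: (x − μ)/(σ + eps) with μ, σ over the configured
    scope (whole volume, or nonzero voxels only for skull-stripped data)."""
    grid = np.asarray(grid, dtype=np.float32)
    if config.normalize_scope == "nonzero_only":
        sel = grid[grid != 0]
        if sel.size == 0:
            sel = grid.reshape(-1)
    else:
        sel = grid.reshape(-1)
    mu = float(sel.mean())
    sigma = float(sel.std())
    return ((grid - mu) / (sigma + config.eps)).astype(np.float32)


def preprocess_case(case: Case, config: PreprocessConfig
                    ) -> tuple[np.ndarray, Optional[np.ndarray], CropBox]:
    """crop → resize → normalize for a whole case.

    Returns ``(images (M, D, H', W') float32, labels (D, H', W') or None,
    crop box)`` with H', W' = config.target_axial.
    """
    volume, truth, box = crop_roi(case.volume, case.truth)
    imgs = []
    for img in volume.images:
        r = resize_axial(img, config.target_axial, kind="image")
        imgs.append(zscore_normalize(r, config))
    labels = None
    if truth is not None:
        labels = resize_axial(truth.labels, config.target_axial, kind="label")
    return np.stack(imgs, axis=0), labels, box


# ---------------------------------------------------------------------------
# Depth windows
# ---------------------------------------------------------------------------

def depth_windows(depth: int, patch_depth: int, stride: Optional[int] = None
                  ) -> tuple[list[tuple[int, int]], int]:
    """Half-open depth ranges covering [0, depth); default stride equals
    patch_depth (non-overlapping tiling). Returns (ranges, tail_pad): ranges
    may extend past ``depth`` by ``tail_pad`` zero slices."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    stride = patch_depth if stride is None else int(stride)
    if stride < 1 or stride > patch_depth:
        raise ValueError("stride must be in [1, patch_depth]")
    ranges = []
    start = 0
    while True:
        ranges.append((start, start + patch_depth))
        if start + patch_depth >= depth:
            break
        start += stride
    tail_pad = ranges[-1][1] - depth
    return ranges, tail_pad


def extract_patches(images: np.ndarray, labels: Optional[np.ndarray],
                    patch_depth: int, stride: Optional[int] = None
                    ) -> list[dict]:
    """Cut (M, D, H, W) images (+ optional labels) into depth windows.

    Each returned dict has ``images`` (M, patch_depth, H, W), optional
    ``labels``, the half-open ``range`` and the zero-``pad`` length (tail
    window only).
    """
    depth = images.shape[1]
    ranges, _ = depth_windows(depth, patch_depth, stride)
    patches = []
    for (a, b) in ranges:
        stop = min(b, depth)
        pad = b - stop
        img = images[:, a:stop]
        if pad:
            img = np.pad(img, ((0, 0), (0, pad), (0, 0), (0, 0)))
        entry = {"images": img, "range": (a, b), "pad": pad}
        if labels is not None:
            lab = labels[a:stop]
            if pad:
                lab = np.pad(lab, ((0, pad), (0, 0), (0, 0)))
            entry["labels"] = lab
        patches.append(entry)
    return patches


def reassemble_patches(prob_patches: Sequence[np.ndarray],
                       ranges: Sequence[tuple[int, int]],
                       original_depth: int) -> np.ndarray:
    """Stitch per-window class probabilities (K, patch_depth, H, W) back into
    a whole-volume (K, original_depth, H, W) array; overlapping voxels are
    averaged, padding is stripped, and gaps raise CoverageError."""
    if len(prob_patches) != len(ranges):
        raise ValueError("one probability block per range required")
    k, _, h, w = prob_patches[0].shape
    padded_depth = max(b for _, b in ranges)
    acc = np.zeros((k, padded_depth, h, w), dtype=np.float64)
    count = np.zeros(padded_depth, dtype=np.int64)
    for probs, (a, b) in zip(prob_patches, ranges):
        if probs.shape[1] != b - a:
            raise ValueError(f"block depth {probs.shape[1]} != range {b - a}")
        acc[:, a:b] += probs
        count[a:b] += 1
    if np.any(count[:original_depth] == 0):
        raise CoverageError("patch ranges leave uncovered slices")
    acc[:, :original_depth] /= count[:original_depth][None, :, None, None]
    return acc[:, :original_depth].astype(np.float32)
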