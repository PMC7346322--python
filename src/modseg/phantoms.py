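"""Synthetic multi-modal phantoms with known ground truth.

Real multi-sequence MR of gliomas has two properties the rest of this
package depends on: (i) the tumor compartments form (approximately) nested
regions, so that whole-tumor ⊇ tumor-core ⊇ enhancing-tumor evaluation
groupings are meaningful, and (ii) each tissue class is conspicuous in a
designated subset of modalities (edema in T2/FLAIR, enhancing tumor in
contrast-enhanced T1). The phantom generator reproduces exactly these two
properties — nested ellipsoidal lesions on a uniform background, and a
per-class-per-modality mean-intensity ("contrast") matrix with additive
Gaussian noise — and nothing else: no bias fields, no anatomy, no partial
volume. Rician noise is a documented extension point.

Everything is deterministic under ``PhantomSpec.seed``; per-case seeds are
derived with ``numpy.random.SeedSequence`` so cases are independent yet
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np

from .volumes import (Case, LabelVolume, MultiModalVolume, write_case_manifest,
                      write_volume)


class GeometryError(ValueError):
    """Requested lesion radii cannot fit inside the volume."""


@dataclass
class PhantomSpec:
    """Study conditions for one phantom family.

    contrast[k, m] is the mean intensity of class k in modality m (class 0 is
    background). noise_sigma is the additive Gaussian std in the same
    arbitrary intensity units.
    """

    dims: tuple[int, int, int] = (16, 48, 48)           # (D, H, W)
    n_modalities: int = 2
    n_classes: int = 3
    contrast: np.ndarray | None = None
    noise_sigma: float = 10.0
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (5.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.contrast is None:
            self.contrast = brats_like_contrast(self.n_classes, self.n_modalities)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        if self.contrast.shape != (self.n_classes, self.n_modalities):
            raise ValueError(
                f"contrast matrix shape {self.contrast.shape} != "
                f"(n_classes={self.n_classes}, n_modalities={self.n_modalities})")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        # A foreground class whose row equals background everywhere is
        # unlearnable; warn rather than refuse (it is a legitimate control).
        for k in range(1, self.n_classes):
            if np.allclose(self.contrast[k], self.contrast[0]):
                warnings.warn(f"class {k} has background contrast in every "
                              "modality and is unlearnable", stacklevel=2)


def brats_like_contrast(n_classes: int, n_modalities: int,
                        background: float = 20.0, dim: float = 45.0,
                        bright: float = 110.0) -> np.ndarray:
    """Default contrast: class k is bright in modality k-1 (mod M), dim in
    the others — each tissue class conspicuous in a designated modality."""
    c = np.full((n_classes, n_modalities), background)
    for k in range(1, n_classes):
        c[k, :] = dim
        c[k, (k - 1) % n_modalities] = bright
    return c


def single_modality_contrast(n_classes: int, n_modalities: int,
                             informative: int = 0, background: float = 20.0,
                             step: float = 45.0) -> np.ndarray:
    """Asymmetric contrast: all class information lives in one modality; the
    other modalities see a flat background (pure noise carriers)."""
    c = np.full((n_classes, n_modalities), background)
    for k in range(1, n_classes):
        c[k, informative] = background + step * k
    return c


# ---------------------------------------------------------------------------
# Label geometry
# ---------------------------------------------------------------------------

def _ellipsoid_mask(dims, center, semi_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[:dims[0], :dims[1], :dims[2]]
    return (((zz - center[0]) / semi_axes[0]) ** 2
            + ((yy - center[1]) / semi_axes[1]) ** 2
            + ((xx - center[2]) / semi_axes[2]) ** 2) <= 1.0


def generate_label_phantom(spec: PhantomSpec,
                           rng: np.random.Generator | None = None) -> LabelVolume:
    """Draw a background-dominated label grid with nested ellipsoidal lesions.

    Each lesion is a stack of concentric ellipsoids: class 1 outermost down
    to class K-1 innermost (shell k+1 strictly inside shell k), mirroring
    the nesting the region groupings assume. Deterministic under spec.seed.
    """
    if any(d < 8 for d in spec.dims):
        raise ValueError("phantom dims must each be >= 8")
    r_lo, r_hi = spec.lesion_radius_range
    if r_hi >= min(spec.dims[1], spec.dims[2]) / 2.0:
        raise GeometryError(
            f"max lesion radius {r_hi} does not fit in the axial plane of "
            f"dims {spec.dims}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    labels = np.zeros(spec.dims, dtype=np.int16)
    n_lesions = int(rng.integers(spec.lesion_count_range[0],
                                 spec.lesion_count_range[1] + 1))
    k_max = spec.n_classes - 1
    for _ in range(n_lesions):
        r = float(rng.uniform(r_lo, r_hi))
        # in-plane centers keep the lesion inside the field of view; along
        # the shallow slice axis lesions may be truncated by the volume
        # border, as real tumors are by the imaging stack
        center = []
        for axis, d in enumerate(spec.dims):
            margin = min(r + 1, d / 2)
            center.append(float(rng.uniform(margin, d - margin)))
        aniso = rng.uniform(0.7, 1.3, size=3)
        # aspect-ratio scaling for anisotropic grids: radius is in voxels of
        # the in-plane axes; depth axis shares the same voxel radius
        for k in range(1, k_max + 1):
            frac = (k_max - k + 1) / k_max      # 1.0 outermost .. 1/k_max
            semi = np.maximum(r * frac * aniso, 1.0)
            mask = _ellipsoid_mask(spec.dims, center, semi)
            labels[mask] = k
    return LabelVolume(labels,
                       label_vocabulary=frozenset(range(spec.n_classes)))


def render_modalities(truth: LabelVolume, spec: PhantomSpec,
                      rng: np.random.Generator | None = None) -> MultiModalVolume:
    """Map labels through the contrast matrix and add Gaussian noise.

    With noise_sigma == 0 the output is the exact per-voxel lookup
    ``contrast[label, m]``.
    """
    if truth.labels.max(initial=0) >= spec.n_classes:
        raise ValueError("truth labels exceed spec.n_classes")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    names = [f"mod{m}" for m in range(spec.n_modalities)]
    images = []
    for m in range(spec.n_modalities):
        img = spec.contrast[truth.labels, m]
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        images.append(img.astype(np.float32))
    return MultiModalVolume(names, images)


def generate_case(spec: PhantomSpec, case_index: int = 0,
                  case_id: str | None = None) -> Case:
    """One fully in-memory phantom case; seed derived from (spec.seed, index)."""
    ss = np.random.SeedSequence([spec.seed, case_index])
    rng_labels, rng_noise = [np.random.default_rng(c) for c in ss.spawn(2)]
    truth = generate_label_phantom(spec, rng=rng_labels)
    volume = render_modalities(truth, spec, rng=rng_noise)
    return Case(id=case_id or f"phantom{case_index:03d}", volume=volume,
                truth=truth)


def generate_dataset(n_cases: int, spec: PhantomSpec,
                     out_dir: str | Path, fmt: str = "nifti") -> list[Path]:
    """Write ``n_cases`` phantom cases + YAML manifests under ``out_dir``.

    Re-running with the same spec produces byte-identical label files.
    Returns the manifest paths in case order.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out_dir = Path(out_dir)
    suffix = ".nii.gz" if fmt == "nifti" else ".mha"
    manifests = []
    for i in range(n_cases):
        case = generate_case(spec, i)
        cdir = out_dir / case.id
        paths = {}
        for name, img in zip(case.volume.modality_names, case.volume.images):
            p = write_volume(img, case.volume.spacing, cdir / f"{name}{suffix}")
            paths[name] = str(p.relative_to(out_dir))
        tpath = write_volume(case.truth.labels, case.volume.spacing,
                             cdir / f"truth{suffix}")
        manifests.append(write_case_manifest(
            case.id, paths, str(tpath.relative_to(out_dir)),
            out_dir / f"{case.id}.yaml"))
    return manifests
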