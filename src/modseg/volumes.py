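"""Reading, writing and validating co-registered multi-modal volume cases.

Volumes are held internally as numpy arrays in ``(D, H, W)`` order: axial
slice index first, then in-plane rows and columns. For skull-stripped brain
MR data in the BRATS-2015 layout, the 155-slice axis is ``D``. NIfTI and
MetaImage files are supported through nibabel and SimpleITK respectively;
orientation metadata is read but never resampled — the pipeline assumes the
modalities of a case were already co-registered.

A *case* pairs an ordered set of modality images (e.g. T1, T1c, T2, FLAIR)
with an optional integer ground-truth label volume. Cases are described on
disk by a small YAML manifest mapping modality names to file paths.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

#: Ground-truth vocabulary for BRATS-2015 style annotations:
#: 0 background, 1 necrosis, 2 edema, 3 non-enhancing tumor, 4 enhancing tumor.
DEFAULT_LABEL_VOCABULARY = frozenset({0, 1, 2, 3, 4})

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_MHA_SUFFIXES = (".mha", ".mhd")


class VolumeFormatError(ValueError):
    """File exists but is not a readable volume of a supported format."""


class CoRegistrationError(ValueError):
    """Modalities (or truth) of one case disagree in spatial dimensions."""


class MissingModalityError(FileNotFoundError):
    """A named modality has no file. Test-time behaviour of multi-path
    networks degrades badly under missing or re-ordered modalities, so this
    fails loudly instead of imputing."""


@dataclass
class MultiModalVolume:
    """M co-registered scalar volumes of one subject, ordered by modality."""

    modality_names: list[str]
    images: list[np.ndarray]          # each (D, H, W) float32
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.modality_names) != len(self.images):
            raise ValueError("one image per modality name required")
        if not self.images:
            raise ValueError("at least one modality required")
        shape = self.images[0].shape
        for name, img in zip(self.modality_names, self.images):
            if img.ndim != 3:
                raise ValueError(f"modality {name!r} is not 3-D")
            if img.shape != shape:
                raise CoRegistrationError(
                    f"modality {name!r} has shape {img.shape}, expected {shape}")
            if not np.all(np.isfinite(img)):
                raise ValueError(f"modality {name!r} contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def n_modalities(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.images[0].shape


@dataclass
class LabelVolume:
    """Integer class labels aligned with a MultiModalVolume."""

    labels: np.ndarray                # (D, H, W) integer
    label_vocabulary: frozenset[int] = DEFAULT_LABEL_VOCABULARY

    def __post_init__(self):
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("label grid must be integer typed")
        present = set(np.unique(self.labels).tolist())
        extra = present - set(self.label_vocabulary)
        if extra:
            raise ValueError(f"labels {sorted(extra)} outside vocabulary "
                             f"{sorted(self.label_vocabulary)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class Case:
    """One subject: images plus (optionally, at test time) ground truth."""

    id: str
    volume: MultiModalVolume
    truth: Optional[LabelVolume] = None

    def __post_init__(self):
        if self.truth is not None and self.truth.shape != self.volume.shape:
            raise CoRegistrationError(
                f"truth shape {self.truth.shape} != volume shape {self.volume.shape}")


# ---------------------------------------------------------------------------
# File round trip
# ---------------------------------------------------------------------------

def _detect_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint in ("nifti", "mha"):
        return format_hint
    name = path.name.lower()
    if any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        return "nifti"
    if any(name.endswith(s) for s in _MHA_SUFFIXES):
        return "mha"
    raise VolumeFormatError(f"cannot infer volume format from {path.name!r}")


def read_volume(path: str | os.PathLike, format_hint: Optional[str] = None
                ) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read one scalar volume; returns ``(grid (D,H,W), spacing mm)``.

    NIfTI data is stored (W, H, D) on disk (fastest axis first), so the array
    is transposed into the package's (D, H, W) convention; SimpleITK already
    yields (D, H, W).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    try:
        if fmt == "nifti":
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
            if data.ndim != 3:
                raise VolumeFormatError(f"{path.name}: payload is {data.ndim}-D, "
                                        "expected 3-D")
            zooms = img.header.get_zooms()[:3]
            return np.ascontiguousarray(data.T), tuple(float(z) for z in zooms[::-1])
        itk = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(itk)
        if data.ndim != 3:
            raise VolumeFormatError(f"{path.name}: payload is {data.ndim}-D, "
                                    "expected 3-D")
        return np.ascontiguousarray(data), tuple(float(s) for s in itk.GetSpacing()[::-1])
    except VolumeFormatError:
        raise
    except Exception as exc:  # unreadable / wrong format payloads
        raise VolumeFormatError(f"could not read {path} as {fmt}: {exc}") from exc


def write_volume(grid: np.ndarray, spacing, path: str | os.PathLike,
                 format: Optional[str] = None) -> Path:
    """Write one scalar/integer volume; integer grids round-trip bit-equal,
    floats are stored as 32-bit."""
    path = Path(path)
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError("grid must be 3-D")
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid contains non-finite values")
    fmt = _detect_format(path, format)
    if np.issubdtype(grid.dtype, np.integer):
        payload = grid.astype(np.int16)
    else:
        payload = grid.astype(np.float32)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(payload.T), affine)
        img.header.set_zooms(tuple(float(s) for s in spacing[::-1]))
        nib.save(img, str(path))
    else:
        itk = sitk.GetImageFromArray(payload)
        itk.SetSpacing(tuple(float(s) for s in spacing[::-1]))
        sitk.WriteImage(itk, str(path))
    return path


# ---------------------------------------------------------------------------
# Case manifests
# ---------------------------------------------------------------------------

def load_case(manifest: str | os.PathLike | Mapping,
              modality_names: Sequence[str],
              label_vocabulary: frozenset[int] = DEFAULT_LABEL_VOCABULARY) -> Case:
    """Assemble a Case from a YAML manifest (or equivalent mapping).

    The manifest holds ``id``, ``modalities: {name: path}`` and optionally
    ``truth: path``. Modality order follows ``modality_names`` exactly; a
    missing modality raises rather than imputing, and any dimension mismatch
    across files is a co-registration error.
    """
    base = Path(".")
    if not isinstance(manifest, Mapping):
        mpath = Path(manifest)
        with open(mpath) as fh:
            manifest = yaml.safe_load(fh)
        base = mpath.parent
    listed = manifest.get("modalities", {})
    images, spacing = [], None
    for name in modality_names:
        if name not in listed:
            raise MissingModalityError(
                f"case {manifest.get('id')!r}: modality {name!r} not listed")
        fpath = Path(listed[name])
        if not fpath.is_absolute():
            fpath = base / fpath
        if not fpath.exists():
            raise MissingModalityError(
                f"case {manifest.get('id')!r}: file for modality {name!r} "
                f"missing: {fpath}")
        grid, sp = read_volume(fpath)
        images.append(grid.astype(np.float32))
        spacing = spacing or sp
    volume = MultiModalVolume(list(modality_names), images, spacing)
    truth = None
    if manifest.get("truth"):
        tpath = Path(manifest["truth"])
        if not tpath.is_absolute():
            tpath = base / tpath
        tgrid, _ = read_volume(tpath)
        truth = LabelVolume(np.rint(tgrid).astype(np.int16),
                            label_vocabulary=label_vocabulary)
    return Case(id=str(manifest.get("id", "case")), volume=volume, truth=truth)


def write_case_manifest(case_id: str, modality_paths: Mapping[str, str],
                        truth_path: Optional[str], out_path: str | os.PathLike) -> Path:
    out_path = Path(out_path)
    doc = {"id": case_id, "modalities": dict(modality_paths)}
    if truth_path is not None:
        doc["truth"] = truth_path
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return out_path
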