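"""Domain types and I/O for CT volumes, binary masks and seed points.

Conventions
-----------
Arrays are indexed ``(x, y, z)`` with ``z`` the slice (axial) axis; spacing
vectors follow the same order, in mm per voxel.  Voxel indices are 0-based and
the physical position of a voxel center is ``index * spacing (+ origin)``.

Masks use the label alphabet {-1, +1} in memory and {0, 1} on disk.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "CtVolume",
    "BinaryMask",
    "SeedPoint",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_seed",
    "write_seed",
]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


class FormatError(ValueError):
    """Raised for unreadable, unsupported or malformed on-disk data."""


@dataclass
class CtVolume:
    """A 3D scalar image on an anisotropic raster.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Voxel intensities on a Hounsfield-unit-like scale.
    spacing : ndarray, shape (3,)
        Physical voxel size in mm along (x, y, z); all components > 0.
    origin : ndarray, shape (3,), optional
        Physical position of voxel (0, 0, 0) in mm.
    """

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.intensities.ndim != 3:
            raise FormatError(
                f"volume must be 3D, got {self.intensities.ndim} dimensions"
            )
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise FormatError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.intensities)):
            raise FormatError("volume intensities must be finite")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """Per-voxel labels in {-1, +1} on the same raster as a companion volume."""

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.labels.ndim != 3:
            raise FormatError(f"mask must be 3D, got {self.labels.ndim} dimensions")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, (-1, 1))):
            raise FormatError(f"mask labels must be in {{-1,+1}}, got values {vals}")

    @classmethod
    def from_bool(cls, positive: np.ndarray, spacing=None, origin=None) -> "BinaryMask":
        labels = np.where(np.asarray(positive, dtype=bool), 1, -1).astype(np.int8)
        kw = {}
        if spacing is not None:
            kw["spacing"] = spacing
        if origin is not None:
            kw["origin"] = origin
        return cls(labels, **kw)

    @property
    def positive(self) -> np.ndarray:
        """Boolean array of the +1 voxels."""
        return self.labels > 0

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def volume_mm3(self) -> float:
        return float(np.count_nonzero(self.positive) * np.prod(self.spacing))


@dataclass
class SeedPoint:
    """A single user-supplied voxel index marking the nodule."""

    index: np.ndarray

    def __post_init__(self):
        self.index = np.asarray(self.index, dtype=int)
        if self.index.shape != (3,):
            raise FormatError(f"seed index must be a 3-vector, got {self.index}")

    def physical(self, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
        return self.index * np.asarray(spacing, float) + np.asarray(origin, float)

    def check_bounds(self, shape) -> None:
        if np.any(self.index < 0) or np.any(self.index >= np.asarray(shape)):
            raise FormatError(f"seed {tuple(self.index)} outside volume of shape {shape}")


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in _SUPPORTED_EXT):
        raise FormatError(
            f"unsupported image extension on {path.name!r}; expected one of {_SUPPORTED_EXT}"
        )


def read_volume(path) -> CtVolume:
    """Read a 3D NIfTI or MetaImage file.

    The on-disk (z, y, x) array order used by ITK is transposed to this
    package's (x, y, z) convention.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    _check_ext(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - message from ITK
        raise FormatError(f"unreadable image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path} holds a {img.GetDimension()}D image; expected 3D")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return CtVolume(
        intensities=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
    )


def write_volume(vol: CtVolume, path) -> None:
    """Write a volume as NIfTI or MetaImage, preserving spacing and origin."""
    path = Path(path)
    _check_ext(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.intensities.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def read_mask(path) -> BinaryMask:
    """Read a 0/1 volume as a {-1,+1} mask; any other value is rejected."""
    vol = read_volume(path)
    vals = np.unique(vol.intensities)
    if not np.all(np.isin(vals, (0, 1))):
        raise FormatError(f"mask file {path} holds non-binary values {vals[:5]}")
    return BinaryMask.from_bool(vol.intensities > 0, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: BinaryMask, path) -> None:
    """Serialize a mask as a 0/1 uint8 volume."""
    vol = CtVolume(
        intensities=mask.positive.astype(np.uint8),
        spacing=mask.spacing,
        origin=mask.origin,
    )
    write_volume(vol, path)


def read_seed(path) -> SeedPoint:
    """Read one seed point from plain text (``x y z``) or JSON ``{"index": [...]}``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such seed file: {path}")
    text = path.read_text().strip()
    if not text:
        raise FormatError(f"empty seed file: {path}")
    if text.lstrip().startswith("{"):
        try:
            data = json.loads(text)
            index = data["index"]
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"malformed JSON seed file {path}: {exc}") from exc
    else:
        tokens = re.split(r"[\s,;]+", text)
        index = tokens
    if len(index) != 3:
        raise FormatError(
            f"seed file {path} must hold exactly one integer triple, got {len(index)} values"
        )
    try:
        triple = [int(v) for v in index]
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-integer seed coordinates in {path}") from exc
    return SeedPoint(np.array(triple))


def write_seed(seed: SeedPoint, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps({"index": [int(v) for v in seed.index]}) + "\n")
    else:
        path.write_text(" ".join(str(int(v)) for v in seed.index) + "\n")
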