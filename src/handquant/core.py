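"""Core domain types for hand-MRI quantification.

Volumes are 3-D scalar grids with physical voxel spacing.  The array axis
order is fixed as ``(slice, row, col)``: axis 0 is the scanner z / slice
direction, axes 1-2 are the in-plane rows and columns.  ``spacing`` is
``(dx, dy, dz)`` in millimetres, where ``dx``/``dy`` are the in-plane column
and row spacings and ``dz`` is the slice thickness, so a clinical hand
protocol with 0.5 x 0.5 mm in-plane resolution and 3.0 mm slices has
``spacing == (0.5, 0.5, 3.0)``.

On disk everything is NIfTI-1 (via nibabel); masks are stored as unsigned
8-bit integers, scalar volumes as 32-bit floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "HandQuantError",
    "ConfigError",
    "DataError",
    "FormatError",
    "GeometryError",
    "DegenerateInputError",
    "InsufficientDataError",
    "SegmentationError",
    "RegistrationError",
    "ModelError",
    "VolumeImage",
    "BinaryMask",
    "AnalysisBounds",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "voxel_volume",
    "to_sitk",
    "from_sitk",
    "dice_coefficient",
    "transform_discrepancy",
]


# ---------------------------------------------------------------------------
# Errors.  Exit-code mapping used by the CLI: ConfigError -> 2,
# DataError (and subclasses) -> 3, numerical failures -> 4.
# ---------------------------------------------------------------------------

class HandQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(HandQuantError):
    """Invalid or inconsistent configuration."""


class DataError(HandQuantError):
    """Invalid input data."""


class FormatError(DataError):
    """File exists but is not a usable 3-D image."""


class GeometryError(DataError):
    """Images expected on the same grid are not."""


class DegenerateInputError(DataError):
    """Input is formally valid but carries no usable signal (e.g. all zero)."""


class InsufficientDataError(DataError):
    """Too few samples for a reliable estimate."""


class SegmentationError(HandQuantError):
    """A segmentation stage produced no usable result."""


class RegistrationError(HandQuantError):
    """Rigid registration failed (no overlap or diverged)."""


class ModelError(HandQuantError):
    """Statistical model cannot be fitted on the given records."""


# ---------------------------------------------------------------------------
# Grid helpers
# ---------------------------------------------------------------------------

_GRID_ATOL = 1e-6


def _as_tuple3(v: Sequence[float], name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


def _check_grid(a: "VolumeImage | BinaryMask", b: "VolumeImage | BinaryMask") -> None:
    if a.data.shape != b.data.shape:
        raise GeometryError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=_GRID_ATOL):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
    if not np.allclose(a.origin, b.origin, atol=_GRID_ATOL):
        raise GeometryError(f"origin mismatch: {a.origin} vs {b.origin}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class VolumeImage:
    """3-D scalar image with physical voxel spacing.

    Parameters
    ----------
    data
        3-D array in ``(slice, row, col)`` order.
    spacing
        ``(dx, dy, dz)`` voxel spacing in mm (col, row, slice directions).
    origin
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise FormatError(f"expected a 3-D volume, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise FormatError("volume contains non-finite values")
        spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be positive, got {spacing}")
        origin = _as_tuple3(self.origin, "origin")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        return replace(self, data=data)

    def same_grid(self, other: "VolumeImage | BinaryMask") -> bool:
        try:
            _check_grid(self, other)
        except GeometryError:
            return False
        return True


@dataclass(frozen=True, eq=False)
class BinaryMask:
    """0/1 volume on a reference image grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise FormatError(f"expected a 3-D mask, got shape {data.shape}")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
        object.__setattr__(self, "data", data.astype(np.uint8, copy=False))
        object.__setattr__(self, "spacing", _as_tuple3(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_tuple3(self.origin, "origin"))

    @classmethod
    def like(cls, ref: VolumeImage, data: np.ndarray) -> "BinaryMask":
        """Mask on the grid of ``ref``; shape must match exactly."""
        if data.shape != ref.data.shape:
            raise GeometryError(f"mask shape {data.shape} != image shape {ref.data.shape}")
        return cls(data=data, spacing=ref.spacing, origin=ref.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def is_subset_of(self, other: "BinaryMask") -> bool:
        _check_grid(self, other)
        return bool(np.all(other.data[self.data > 0] == 1))

    def same_grid(self, other: "VolumeImage | BinaryMask") -> bool:
        try:
            _check_grid(self, other)
        except GeometryError:
            return False
        return True


@dataclass(frozen=True)
class AnalysisBounds:
    """Inclusive slice range bounding the analysis region.

    Mirrors the clinical convention of marking the proximal and distal ends
    of the third metacarpal (MCP III) and restricting all volumetry to the
    slices in between.  Indices are 0-based and inclusive on both ends.
    """

    proximal_slice: int
    distal_slice: int

    def __post_init__(self) -> None:
        if self.proximal_slice < 0 or self.distal_slice < self.proximal_slice:
            raise ValueError(
                f"require 0 <= proximal <= distal, got "
                f"({self.proximal_slice}, {self.distal_slice})"
            )

    def validate_for(self, n_slices: int) -> None:
        if self.distal_slice >= n_slices:
            raise IndexError(
                f"bounds {self} exceed volume with {n_slices} slices"
            )

    def slice_indices(self) -> range:
        return range(self.proximal_slice, self.distal_slice + 1)


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid transform: ZYX Euler rotation about ``center`` plus translation.

    Angles are in degrees, translations and the rotation center in mm.  The
    transform acts on physical points; composition and inversion go through
    SimpleITK so the convention matches the registration/resampling code.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation_deg", _as_tuple3(self.rotation_deg, "rotation"))
        object.__setattr__(self, "translation_mm", _as_tuple3(self.translation_mm, "translation"))
        object.__setattr__(self, "center_mm", _as_tuple3(self.center_mm, "center"))

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter(self.center_mm)
        t.SetRotation(*(math.radians(a) for a in self.rotation_deg))
        t.SetTranslation(self.translation_mm)
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        ang = (t.GetAngleX(), t.GetAngleY(), t.GetAngleZ())
        return cls(
            rotation_deg=tuple(math.degrees(a) for a in ang),  # type: ignore[arg-type]
            translation_mm=tuple(t.GetTranslation()),  # type: ignore[arg-type]
            center_mm=tuple(t.GetCenter()),  # type: ignore[arg-type]
        )

    def inverse(self) -> "RigidTransform":
        inv = sitk.Euler3DTransform(self.to_sitk().GetInverse())
        return RigidTransform.from_sitk(inv)

    def apply_to_point(self, p: Sequence[float]) -> tuple[float, float, float]:
        return tuple(self.to_sitk().TransformPoint(tuple(float(x) for x in p)))  # type: ignore[return-value]

    def is_identity(self, atol_mm: float = 1e-6, atol_deg: float = 1e-6) -> bool:
        origin_shift = self.apply_to_point((0.0, 0.0, 0.0))
        probe = self.apply_to_point((100.0, 100.0, 100.0))
        return (
            max(abs(a) for a in self.rotation_deg) <= atol_deg
            and max(abs(x) for x in origin_shift) <= atol_mm
            and max(abs(p - 100.0) for p in probe) <= atol_mm + 100.0 * math.radians(atol_deg)
        )

    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation_deg=tuple(d["rotation_deg"]),
            translation_mm=tuple(d["translation_mm"]),
            center_mm=tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
        )


# ---------------------------------------------------------------------------
# I/O  (NIfTI-1 via nibabel)
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 volume.

    The file's voxel data are returned in ``(slice, row, col)`` order; spacing
    is taken from the header zooms and the origin from the affine translation.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got {img.ndim}-D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    data = np.asarray(img.dataobj)
    # nibabel stores (x, y, z) fastest-to-slowest; our order is (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VolumeImage(data=data, spacing=zooms, origin=origin)


def write_volume(img: VolumeImage, path: str | Path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 (default 32-bit float)."""
    path = Path(path)
    data = np.transpose(np.asarray(img.data, dtype=dtype), (2, 1, 0))
    nifti = nib.Nifti1Image(data, _affine(img.spacing, img.origin))
    nifti.header.set_zooms(img.spacing)
    try:
        nib.save(nifti, str(path))
    except Exception as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask from NIfTI-1; any nonzero voxel becomes 1."""
    vol = read_volume(path)
    return BinaryMask(data=(vol.data > 0.5), spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as 8-bit NIfTI-1."""
    write_volume(
        VolumeImage(data=mask.data, spacing=mask.spacing, origin=mask.origin),
        path,
        dtype=np.uint8,
    )


# ---------------------------------------------------------------------------
# Geometry utilities
# ---------------------------------------------------------------------------

def voxel_volume(img: VolumeImage | BinaryMask) -> float:
    """Physical volume of one voxel in mm^3 (dx * dy * dz)."""
    dx, dy, dz = img.spacing
    return dx * dy * dz


def to_sitk(img: VolumeImage | BinaryMask, dtype=None) -> sitk.Image:
    """Convert to a SimpleITK image (spacing/origin preserved).

    Our ``(slice, row, col)`` array order is exactly SimpleITK's
    ``GetArrayFromImage`` order, and our ``(dx, dy, dz)`` spacing matches
    SimpleITK's ``(x, y, z)``.
    """
    data = img.data if dtype is None else np.asarray(img.data, dtype=dtype)
    im = sitk.GetImageFromArray(data)
    im.SetSpacing(img.spacing)
    im.SetOrigin(img.origin)
    return im


def from_sitk(im: sitk.Image) -> VolumeImage:
    return VolumeImage(
        data=sitk.GetArrayFromImage(im),
        spacing=tuple(im.GetSpacing()),
        origin=tuple(im.GetOrigin()),
    )


def transform_discrepancy(
    a: RigidTransform, b: RigidTransform, points: Iterable[Sequence[float]]
) -> tuple[float, float]:
    """Compare two rigid transforms by their action.

    Returns ``(max_displacement_mm, rotation_angle_deg)``: the largest
    distance between images of the probe points, and the angle of the
    relative rotation.  Parameter-wise comparison would be misleading when
    the two transforms use different rotation centers.
    """
    ta, tb = a.to_sitk(), b.to_sitk()
    max_disp = 0.0
    for p in points:
        pa = np.array(ta.TransformPoint(tuple(float(x) for x in p)))
        pb = np.array(tb.TransformPoint(tuple(float(x) for x in p)))
        max_disp = max(max_disp, float(np.linalg.norm(pa - pb)))
    ra = np.array(ta.GetMatrix()).reshape(3, 3)
    rb = np.array(tb.GetMatrix()).reshape(3, 3)
    cos_theta = (np.trace(ra @ rb.T) - 1.0) / 2.0
    angle = math.degrees(math.acos(min(1.0, max(-1.0, cos_theta))))
    return max_disp, angle


def dice_coefficient(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both are empty."""
    aa = a.as_bool() if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    bb = b.as_bool() if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    if aa.shape != bb.shape:
        raise GeometryError(f"shape mismatch: {aa.shape} vs {bb.shape}")
    denom = int(aa.sum()) + int(bb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(aa, bb).sum()) / denom
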