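"""Volumes, affine geometry, binary masks and the diffusion acquisition scheme.

All world/voxel conversions in the pipeline live here.  Conventions:

* A voxel index ``(i, j, k)`` refers to the voxel *center*; the voxel occupies
  the half-open cube ``[i - 0.5, i + 0.5)`` per axis in continuous index space.
* The world frame is RAS millimetres as given by the affine.  No reorientation
  or resampling is performed: all inputs for one subject must already share a
  world frame (i.e. be coregistered).
* Masks may not contain missing values; scalar maps may carry NaN as a
  missing-value sentinel outside the region of validity, and samplers reject it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    EmptyMaskError,
    FormatError,
    GeometryError,
    OutOfBoundsError,
    ValidationError,
)

__all__ = [
    "Volume",
    "BinaryMask",
    "DiffusionScheme",
    "DWISeries",
    "read_nifti",
    "write_nifti",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "voxel_to_world",
    "world_to_voxel",
    "containing_voxel",
    "mask_voxel_centers_world",
    "mask_volume_cm3",
    "trilinear_sample",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got shape {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise GeometryError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine rotation/scaling block is singular")
    return affine


@dataclass
class Volume:
    """A 3-D scalar grid with a voxel-to-world affine (mm).

    ``unit_label`` is free text describing the physical unit of the voxel
    values (e.g. ``"mm^2/s"`` or ``"dimensionless"``).
    """

    data: np.ndarray
    affine: np.ndarray
    unit_label: str = "dimensionless"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(
                f"volume data must be 3-D with positive extents, got shape {self.data.shape}"
            )
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryMask(Volume):
    """A :class:`Volume` whose data is restricted to {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("mask contains non-finite values")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValidationError(f"mask values must be 0/1, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        """Number of set voxels."""
        return int(self.data.sum())


@dataclass
class DiffusionScheme:
    """b-values (s/mm^2) and unit gradient directions, one entry per volume."""

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (self.bvalues.size, 3):
            raise ValidationError(
                "directions must be (n, 3) matching the number of b-values; "
                f"got {self.directions.shape} for {self.bvalues.size} b-values"
            )
        if np.any(self.bvalues < 0):
            raise ValidationError("b-values must be non-negative")
        dw = self.bvalues > 0
        norms = np.linalg.norm(self.directions[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("nonzero-b directions must have unit norm (±1e-6)")

    def __len__(self) -> int:
        return self.bvalues.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvalues == 0))

    def validate_for_tensor_fit(self) -> None:
        """Require >=6 distinct nonzero-b directions and >=1 b=0 entry."""
        dw = self.directions[self.bvalues > 0]
        # distinct up to sign (antipodal directions probe the same tensor axis)
        distinct: list[np.ndarray] = []
        for g in dw:
            if not any(
                np.allclose(g, h, atol=1e-8) or np.allclose(g, -h, atol=1e-8)
                for h in distinct
            ):
                distinct.append(g)
        if len(distinct) < 6 or self.n_b0 < 1:
            raise ValidationError(
                "tensor fitting needs >=6 distinct nonzero-b directions and >=1 b=0 "
                f"volume; scheme has {len(distinct)} distinct directions and "
                f"{self.n_b0} b=0 volumes"
            )


@dataclass
class DWISeries:
    """4-D diffusion-weighted series (x, y, z, volume) with its scheme."""

    data: np.ndarray
    scheme: DiffusionScheme
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError(f"DWI data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[3] != len(self.scheme):
            raise ValidationError(
                f"4th dimension ({self.data.shape[3]}) must equal scheme length "
                f"({len(self.scheme)})"
            )
        if np.any(self.data < 0):
            raise ValidationError("DWI signal values must be non-negative")
        self.affine = _check_affine(self.affine)


# ---------------------------------------------------------------------------
# NIfTI / scheme I/O
# ---------------------------------------------------------------------------


def read_nifti(path: str | Path) -> Volume:
    """Read a NIfTI-1 volume.

    The affine is taken from the sform when valid, else the qform (this is
    what :mod:`nibabel` exposes as ``img.affine``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3-D volume, got {data.ndim}-D data (dim field)"
        )
    return Volume(data=data, affine=np.asarray(img.affine, dtype=float))


def read_nifti_4d(path: str | Path, scheme: DiffusionScheme) -> DWISeries:
    """Read a 4-D NIfTI DWI series and pair it with its diffusion scheme."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 4-D DWI data, got {data.ndim}-D (dim field)")
    return DWISeries(data=data, scheme=scheme, affine=np.asarray(img.affine, dtype=float))


def write_nifti(volume: Volume | DWISeries, path: str | Path) -> Path:
    """Write a volume (or 4-D series) as NIfTI-1; the affine is preserved."""
    path = Path(path)
    if not path.parent.is_dir():
        raise OSError(f"parent directory does not exist: {path.parent}")
    data = volume.data
    if isinstance(volume, Volume) and not isinstance(volume, BinaryMask):
        pass  # NaN sentinels are allowed in scalar maps
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), volume.affine)
    img.set_sform(volume.affine, code=1)
    img.set_qform(volume.affine, code=1)
    nib.save(img, str(path))
    return path


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> DiffusionScheme:
    """Read an FSL-style bval/bvec text pair (bvec: one row per axis)."""
    try:
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
    except Exception as exc:
        raise FormatError(f"cannot read bval/bvec pair: {exc}") from exc
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DiffusionScheme(bvalues=bvals, directions=bvecs)


def write_bvals_bvecs(
    scheme: DiffusionScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# Affine geometry
# ---------------------------------------------------------------------------


def voxel_to_world(affine: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices to world coordinates (mm).

    ``index`` may be a single 3-vector or an (n, 3) array.
    """
    affine = np.asarray(affine, dtype=float)
    index = np.asarray(index, dtype=float)
    return index @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`voxel_to_world`."""
    affine = _check_affine(affine)
    point = np.asarray(point, dtype=float)
    inv = np.linalg.inv(affine[:3, :3])
    return (point - affine[:3, 3]) @ inv.T


def containing_voxel(affine: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Integer index of the voxel whose half-open cube contains a world point."""
    idx = world_to_voxel(affine, point)
    return np.floor(idx + 0.5).astype(np.int64)


def mask_voxel_centers_world(mask: BinaryMask) -> np.ndarray:
    """World-space centers (mm) of all set voxels; shape (n_set, 3)."""
    ijk = np.argwhere(mask.data > 0)
    if ijk.size == 0:
        raise EmptyMaskError("mask has no set voxels")
    return voxel_to_world(mask.affine, ijk.astype(float))


def mask_volume_cm3(mask: BinaryMask) -> float:
    """Mask volume in cm^3: set-voxel count times voxel volume."""
    voxel_mm3 = abs(np.linalg.det(np.asarray(mask.affine, dtype=float)[:3, :3]))
    return float(mask.data.sum() * voxel_mm3 / 1000.0)


def trilinear_sample(volume: Volume, point: np.ndarray) -> float:
    """Trilinear interpolation of a scalar volume at a world point (mm).

    The point must lie inside the grid's voxel-center bounding box and the 8
    surrounding voxels must be non-missing.
    """
    idx = world_to_voxel(volume.affine, point)
    shape = np.array(volume.shape)
    if np.any(idx < 0) or np.any(idx > shape - 1):
        raise OutOfBoundsError(f"point {np.asarray(point)} maps to index {idx} outside grid")
    lo = np.floor(idx).astype(int)
    lo = np.minimum(lo, shape - 2)  # so lo+1 stays in-grid at the upper face
    lo = np.maximum(lo, 0)
    frac = idx - lo
    out = 0.0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (
                    (frac[0] if di else 1 - frac[0])
                    * (frac[1] if dj else 1 - frac[1])
                    * (frac[2] if dk else 1 - frac[2])
                )
                v = volume.data[lo[0] + di, lo[1] + dj, lo[2] + dk]
                if w > 0 and not np.isfinite(v):
                    raise ValidationError(
                        f"missing-value sentinel at voxel {tuple(lo + [di, dj, dk])}"
                    )
                out += w * (v if np.isfinite(v) else 0.0)
    return float(out)
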