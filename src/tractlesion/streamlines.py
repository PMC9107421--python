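"""Streamline representation, TCK I/O, ROI tract selection, voxel occupancy.

A streamline is an (n, 3) float array of ordered world-space points in mm
(n >= 2).  A :class:`Tractogram` is a list of such arrays plus a free-text
label naming the world frame.  TCK files use the MRtrix track-file dialect:
``mrtrix tracks`` magic line, Float32LE triplets, ``(NaN, NaN, NaN)``
streamline separators and an ``(Inf, Inf, Inf)`` terminator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import EmptyMaskError, FormatError, OutOfBoundsError, ValidationError
from .imaging import BinaryMask, Volume, world_to_voxel

__all__ = [
    "Tractogram",
    "read_tck",
    "write_tck",
    "filter_by_seed_target",
    "tract_voxel_occupancy",
    "resample_streamline",
    "streamline_length",
]


def _check_streamline(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 2:
        raise ValidationError(
            f"a streamline must be an (n>=2, 3) array, got shape {points.shape}"
        )
    if not np.all(np.isfinite(points)):
        raise ValidationError("streamline contains non-finite coordinates")
    if np.allclose(points, points[0]):
        raise ValidationError("all streamline points are identical")
    return points


@dataclass
class Tractogram:
    """An ordered collection of streamlines sharing one world frame."""

    streamlines: list[np.ndarray] = field(default_factory=list)
    frame_label: str = "RAS mm"

    def __post_init__(self) -> None:
        self.streamlines = [_check_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


# ---------------------------------------------------------------------------
# TCK I/O (nibabel.streamlines, MRtrix dialect)
# ---------------------------------------------------------------------------


def read_tck(path: str | Path) -> Tractogram:
    """Read an MRtrix ``.tck`` track file (world-space mm coordinates)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        tck = nib.streamlines.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read TCK file {path}: {exc}") from exc
    if not isinstance(tck, nib.streamlines.TckFile):
        raise FormatError(f"{path} is not an MRtrix TCK file")
    streamlines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    return Tractogram(streamlines=streamlines, frame_label="RAS mm")


def write_tck(tractogram: Tractogram, path: str | Path) -> Path:
    """Write a tractogram as MRtrix ``.tck``; the header ``count`` field
    equals the streamline count."""
    path = Path(path)
    sl = [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines]
    nib_tg = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    tck = nib.streamlines.TckFile(nib_tg, header={"count": len(sl)})
    try:
        tck.save(str(path))
    except Exception as exc:
        raise OSError(f"cannot write TCK file {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# ROI selection and occupancy
# ---------------------------------------------------------------------------


def _points_in_mask(mask: BinaryMask, points: np.ndarray) -> np.ndarray:
    """Boolean array: does each world point fall inside a set voxel?

    Uses the voxel-center convention: point belongs to voxel
    ``floor(index + 0.5)`` of its continuous index.
    """
    idx = np.floor(world_to_voxel(mask.affine, np.atleast_2d(points)) + 0.5).astype(int)
    shape = np.array(mask.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(idx), dtype=bool)
    if inside.any():
        ii = idx[inside]
        out[inside] = mask.data[ii[:, 0], ii[:, 1], ii[:, 2]] > 0
    return out


def filter_by_seed_target(
    tractogram: Tractogram,
    seed: BinaryMask,
    target: BinaryMask,
    mode: str = "endpoint",
) -> Tractogram:
    """Keep streamlines connecting the seed and target ROIs.

    ``mode="endpoint"`` (default, the strict reading): one endpoint inside the
    seed mask and the other inside the target, in either orientation.
    ``mode="traverse"``: any vertex inside the seed and any vertex inside the
    target suffices.
    """
    if seed.n_voxels == 0 or target.n_voxels == 0:
        raise EmptyMaskError("seed and target masks must be nonempty")
    if mode not in ("endpoint", "traverse"):
        raise ValidationError(f"unknown selection mode {mode!r}")
    kept = []
    for s in tractogram.streamlines:
        if mode == "endpoint":
            ends = np.vstack([s[0], s[-1]])
            in_seed = _points_in_mask(seed, ends)
            in_target = _points_in_mask(target, ends)
            ok = (in_seed[0] and in_target[1]) or (in_seed[1] and in_target[0])
        else:
            ok = _points_in_mask(seed, s).any() and _points_in_mask(target, s).any()
        if ok:
            kept.append(s)
    return Tractogram(streamlines=kept, frame_label=tractogram.frame_label)


def tract_voxel_occupancy(tractogram: Tractogram, reference: Volume) -> BinaryMask:
    """Binary mask of voxels containing at least one streamline vertex.

    Vertex-based: voxels are those containing a vertex under the reference
    affine and the half-open center convention; segments between vertices are
    not rasterised.  Resample streamlines to at most half the voxel size
    beforehand if segment-level coverage is needed.
    """
    if len(tractogram) == 0:
        raise ValidationError("tractogram is empty")
    shape = np.array(reference.shape)
    out = np.zeros(reference.shape, dtype=np.uint8)
    for si, s in enumerate(tractogram.streamlines):
        idx = np.floor(world_to_voxel(reference.affine, s) + 0.5).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise OutOfBoundsError(
                f"streamline {si} has vertices outside the reference grid"
            )
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return BinaryMask(data=out, affine=reference.affine)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def streamline_length(points: np.ndarray) -> float:
    """Total arc length (mm) of a polyline."""
    return float(np.linalg.norm(np.diff(np.asarray(points, float), axis=0), axis=1).sum())


def resample_streamline(streamline: np.ndarray, step: float) -> np.ndarray:
    """Subdivide each segment so the vertex spacing is at most ``step`` mm.

    Original vertices (in particular both endpoints) are preserved exactly, so
    the polyline and its arc length are unchanged; only the vertex density
    increases.  Each segment of length L is split into ceil(L / step) equal
    pieces.
    """
    if step <= 0:
        raise ValidationError(f"step must be positive, got {step}")
    points = _check_streamline(streamline)
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / step - 1e-12)))
        for t in range(1, n + 1):
            out.append(a + (b - a) * (t / n))
    return np.asarray(out)
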