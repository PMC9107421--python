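"""Diffusion tensor estimation and tract-averaged FA / MD.

The single-tensor model is fitted per voxel by least squares on log-signals:

    log S(g) = log S0 - b * g' D g

with design unknowns ``(log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``.  Fractional
anisotropy and mean diffusivity follow from the tensor eigenvalues
(descending, clamped at zero):

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / sqrt(l1^2+l2^2+l3^2)
    MD = (l1 + l2 + l3) / 3

Tract averaging is over the *unique* voxels of the tract occupancy mask,
unweighted by how many streamline vertices visit a voxel (a per-vertex
weighted variant is available via ``weights``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DesignMatrixError, ValidationError
from .imaging import BinaryMask, DWISeries, Volume

__all__ = [
    "TensorField",
    "IntegrityResult",
    "tensor_design_matrix",
    "fit_tensors",
    "tensor_eigenvalues",
    "fractional_anisotropy",
    "mean_diffusivity",
    "scalar_map",
    "tract_mean_scalar",
]

# component order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (mm^2/s) on a validity mask.

    ``components`` has shape (X, Y, Z, 6) ordered (Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz); tensors are defined exactly where ``valid`` is True.  ``clamped``
    flags voxels where non-positive signals had to be clamped before the log.
    """

    components: np.ndarray
    valid: np.ndarray
    affine: np.ndarray
    clamped: np.ndarray | None = None

    def tensor_at(self, i: int, j: int, k: int) -> np.ndarray:
        """Full symmetric 3x3 tensor at one voxel."""
        if not self.valid[i, j, k]:
            raise ValidationError(f"voxel ({i},{j},{k}) is outside the validity mask")
        return six_to_matrix(self.components[i, j, k])


@dataclass(frozen=True)
class IntegrityResult:
    """Tract-averaged structural integrity measures."""

    mean_fa: float
    mean_md: float
    n_voxels: int


def six_to_matrix(six: np.ndarray) -> np.ndarray:
    """(..., 6) components -> (..., 3, 3) symmetric matrices."""
    six = np.asarray(six, dtype=float)
    xx, yy, zz, xy, xz, yz = np.moveaxis(six, -1, 0)
    m = np.empty(six.shape[:-1] + (3, 3))
    m[..., 0, 0] = xx
    m[..., 1, 1] = yy
    m[..., 2, 2] = zz
    m[..., 0, 1] = m[..., 1, 0] = xy
    m[..., 0, 2] = m[..., 2, 0] = xz
    m[..., 1, 2] = m[..., 2, 1] = yz
    return m


def matrix_to_six(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


def tensor_design_matrix(scheme) -> np.ndarray:
    """(n_volumes, 7) design for the log-linear tensor fit.

    Row i: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz],
    acting on unknowns (log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).  b=0 rows
    contribute zero diffusion weighting (no pre-averaging of b=0 volumes).
    """
    b = scheme.bvalues
    g = scheme.directions
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensors(
    dwi: DWISeries,
    brain: BinaryMask,
    *,
    weighted: bool = False,
    clamp_eps: float = 1e-10,
) -> TensorField:
    """Least-squares tensor fit on log-signals for every brain-mask voxel.

    ``weighted=True`` performs one step of weighted least squares with weights
    equal to the squared predicted signals from the ordinary fit.  Signals
    <= 0 are clamped to ``clamp_eps`` before the log and the voxel is flagged
    in ``clamped``.
    """
    dwi.scheme.validate_for_tensor_fit()
    if len(dwi.scheme) < 7:
        raise DesignMatrixError(
            f"need at least 7 volumes to fit 7 unknowns, got {len(dwi.scheme)}"
        )
    if brain.shape != dwi.data.shape[:3]:
        raise ValidationError("brain mask grid does not match the DWI grid")
    design = tensor_design_matrix(dwi.scheme)
    if np.linalg.matrix_rank(design) < 7:
        raise DesignMatrixError("diffusion scheme gives a rank-deficient design matrix")

    mask = brain.data > 0
    signals = dwi.data[mask]  # (n_vox, n_vol)
    clamped_vox = np.any(signals <= 0, axis=1)
    log_s = np.log(np.maximum(signals, clamp_eps))
    # one pinv solves every voxel at once
    pinv = np.linalg.pinv(design)
    coefs = log_s @ pinv.T  # (n_vox, 7)
    if weighted:
        pred = np.exp(coefs @ design.T)  # (n_vox, n_vol)
        w = pred**2
        # per-voxel WLS solve; loop kept simple, n_vox is modest in practice
        for v in range(coefs.shape[0]):
            dw = design * w[v, :, None]
            coefs[v] = np.linalg.lstsq(design.T @ dw, dw.T @ log_s[v], rcond=None)[0]

    components = np.zeros(dwi.data.shape[:3] + (6,))
    components[mask] = coefs[:, 1:]
    clamped = np.zeros(dwi.data.shape[:3], dtype=bool)
    clamped[mask] = clamped_vox
    return TensorField(components=components, valid=mask, affine=dwi.affine, clamped=clamped)


def tensor_eigenvalues(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric tensor, descending; negatives clamped to 0.

    Accepts a length-6 component vector (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) or a
    3x3 symmetric matrix, or arrays thereof (leading axes preserved).
    """
    tensor = np.asarray(tensor, dtype=float)
    if not np.all(np.isfinite(tensor)):
        raise ValidationError("tensor has non-finite components")
    if tensor.shape[-1] == 6 and (tensor.ndim == 1 or tensor.shape[-2:] != (3, 3)):
        tensor = six_to_matrix(tensor)
    eigs = np.linalg.eigvalsh(tensor)[..., ::-1]  # descending
    return np.clip(eigs, 0.0, None)


def fractional_anisotropy(eigs: np.ndarray) -> np.ndarray | float:
    """FA in [0, 1] from (clamped, non-negative) eigenvalue triples.

    FA is scale-invariant; the all-zero triple is defined as FA = 0.
    """
    eigs = np.asarray(eigs, dtype=float)
    l1, l2, l3 = eigs[..., 0], eigs[..., 1], eigs[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1), 0.0))
    fa = np.clip(fa, 0.0, 1.0)
    return float(fa) if fa.ndim == 0 else fa


def mean_diffusivity(eigs: np.ndarray) -> np.ndarray | float:
    """MD (mm^2/s): arithmetic mean of the eigenvalues (= trace / 3)."""
    eigs = np.asarray(eigs, dtype=float)
    md = eigs.mean(axis=-1)
    return float(md) if md.ndim == 0 else md


def scalar_map(field: TensorField, metric: str) -> Volume:
    """Voxel-wise FA or MD map; NaN sentinel outside the validity mask."""
    metric = metric.upper()
    if metric not in ("FA", "MD"):
        raise ValidationError(f"unknown metric {metric!r}; expected 'FA' or 'MD'")
    out = np.full(field.valid.shape, np.nan)
    eigs = tensor_eigenvalues(field.components[field.valid])
    if metric == "FA":
        out[field.valid] = fractional_anisotropy(eigs)
        unit = "dimensionless"
    else:
        out[field.valid] = mean_diffusivity(eigs)
        unit = "mm^2/s"
    return Volume(data=out, affine=field.affine, unit_label=unit)


def tract_mean_scalar(
    map_volume: Volume,
    occupancy: BinaryMask,
    weights: np.ndarray | None = None,
) -> tuple[float, int]:
    """Unweighted mean of a scalar map over the unique occupied voxels.

    Returns ``(mean, n_voxels)``.  ``weights`` (same grid, e.g. per-voxel
    vertex visitation counts) switches to a weighted mean.  Any occupied voxel
    carrying the NaN sentinel is an error.
    """
    if occupancy.shape != map_volume.shape:
        raise ValidationError("occupancy mask grid does not match the scalar map")
    sel = occupancy.data > 0
    n = int(sel.sum())
    if n == 0:
        raise ValidationError("occupancy mask is empty")
    vals = map_volume.data[sel]
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(sel & ~np.isfinite(map_volume.data))[0]
        raise ValidationError(
            f"occupied voxel {tuple(bad)} carries the missing-value sentinel"
        )
    if weights is None:
        return float(vals.mean()), n
    w = np.asarray(weights, dtype=float)[sel]
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be non-negative with positive sum")
    return float(np.average(vals, weights=w)), n


def tract_integrity(
    fa_map: Volume, md_map: Volume, occupancy: BinaryMask
) -> IntegrityResult:
    """Convenience: tract-averaged FA and MD over one occupancy mask."""
    mean_fa, n = tract_mean_scalar(fa_map, occupancy)
    mean_md, _ = tract_mean_scalar(md_map, occupancy)
    return IntegrityResult(mean_fa=mean_fa, mean_md=mean_md, n_voxels=n)
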