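"""Synthetic phantoms and cohorts with the structure the analysis assumes.

Two generators live here:

* An imaging phantom: an oblique frontal fiber bundle running between two
  box ROIs (standing in for pre-SMA/SMA and pars opercularis/triangularis),
  a spherical tumor at a controlled distance with an optional oedema shell,
  a prolate-tensor field aligned to the bundle, and a simulated
  diffusion-weighted series on the matching acquisition scheme
  (b=1500 s/mm^2, 50 directions, 6 b=0 volumes, 2 mm isotropic voxels).

* A cohort: subjects with clinical covariates, ipsilateral tract metrics and
  six cognitive z-scores in which scores depend linearly on tract-tumor
  distance and/or tract MD with configurable, hemisphere-specific effect
  sizes.  The defaults mirror the study conditions the pipeline targets:
  32 right- and 40 left-hemisphere tumors, a distance effect of
  0.061 z/mm and an MD effect of -0.302 z per 1e-4 mm^2/s on shifting
  attention, planted in the right hemisphere only.

All generators are deterministic given their config (including its seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .imaging import BinaryMask, DiffusionScheme, DWISeries, voxel_to_world
from .microstructure import TensorField, matrix_to_six, tensor_design_matrix
from .stats import COGNITIVE_TESTS, REVERSED_TESTS, CohortTable
from .streamlines import Tractogram, resample_streamline

__all__ = [
    "PhantomConfig",
    "CohortConfig",
    "default_scheme",
    "make_roi_masks",
    "make_aslant_bundle",
    "make_tumor_mask",
    "make_tensor_phantom",
    "simulate_dwi",
    "simulate_cohort",
    "phantom_with_tumor_gap",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Geometry, tensor and acquisition parameters of the imaging phantom.

    Distances are world-space mm; the grid affine is ``voxel_size_mm`` times
    the identity with zero translation, so voxel (i,j,k) is centered at
    ``voxel_size_mm * (i,j,k)``.
    """

    grid_shape: tuple[int, int, int] = (40, 44, 36)
    voxel_size_mm: float = 2.0
    n_streamlines: int = 50
    seed_center_mm: tuple[float, float, float] | None = None
    target_center_mm: tuple[float, float, float] | None = None
    roi_half_size_mm: float = 8.0
    curvature_mm: float = 10.0
    bundle_radius_mm: float = 4.0
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_radius_mm: float = 8.0
    oedema_shell_mm: float = 4.0
    lambda_parallel: float = 1.5e-3  # mm^2/s
    lambda_perp: float = 3.0e-4
    oedema_md_scale: float = 1.4
    s0: float = 1000.0
    noise_sd: float = 0.0  # Gaussian signal noise, as a fraction of s0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0 or self.bundle_radius_mm <= 0 or self.tumor_radius_mm <= 0:
            raise ValidationError("voxel size and radii must be positive")
        extent = self.extent_mm
        if self.seed_center_mm is None:
            self.seed_center_mm = (0.35 * extent[0], 0.30 * extent[1], 0.85 * extent[2])
        if self.target_center_mm is None:
            self.target_center_mm = (0.35 * extent[0], 0.72 * extent[1], 0.20 * extent[2])
        if self.tumor_center_mm is None:
            # lateral to the bundle midpoint, out along +x
            mid = 0.5 * (np.asarray(self.seed_center_mm) + np.asarray(self.target_center_mm))
            self.tumor_center_mm = tuple(
                mid + np.array([self.bundle_radius_mm + self.tumor_radius_mm + 10.0, 0.0, 0.0])
            )

    @property
    def extent_mm(self) -> np.ndarray:
        """World-space size of the grid (distance spanned by voxel centers)."""
        return (np.asarray(self.grid_shape) - 1) * self.voxel_size_mm

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size_mm
        return a


@dataclass
class CohortConfig:
    """Cohort composition and planted effect sizes.

    ``slope_per_test`` is in z-units per mm of tract-tumor distance;
    ``md_slope_per_test`` in z-units per 1e-4 mm^2/s of tract MD.  Effects
    apply only to subjects whose tumor is in ``effect_hemisphere``
    ("right", "left" or "both").
    """

    n_right: int = 32
    n_left: int = 40
    slope_per_test: dict = field(default_factory=lambda: {"shifting_attention": 0.061})
    md_slope_per_test: dict = field(default_factory=lambda: {"shifting_attention": -0.302})
    effect_hemisphere: str = "right"
    noise_sd: float = 0.9  # z-score residual SD
    grade_effect: float = -0.15  # z per WHO grade step above 2
    volume_effect: float = -0.004  # z per cm^3
    handedness_effect: float = 0.10  # offset for left-handed subjects
    distance_bounds_mm: tuple[float, float] = (1.0, 25.0)
    md_base_e3: float = 0.78  # tract MD far from the tumor, x1e-3 mm^2/s
    md_gain_e3: float = 1.0  # inverse-distance oedema coupling strength
    md_floor_mm: float = 3.0
    md_noise_e3: float = 0.05
    missing_letter_fluency_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_right <= 0 or self.n_left <= 0:
            raise ValidationError("cohort sizes must be positive")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 0 <= self.missing_letter_fluency_fraction < 1:
            raise ValidationError("missing fraction must be in [0, 1)")
        if self.effect_hemisphere not in ("right", "left", "both"):
            raise ValidationError("effect_hemisphere must be right/left/both")


# ---------------------------------------------------------------------------
# Acquisition scheme
# ---------------------------------------------------------------------------


def default_scheme(n_directions: int = 50, n_b0: int = 6, b: float = 1500.0) -> DiffusionScheme:
    """6 b=0 entries plus 50 unit directions at b=1500 s/mm^2.

    Directions come from a deterministic spherical Fibonacci lattice, which
    spreads points nearly uniformly without iterative optimisation.
    """
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_directions)
    z = 1.0 - (2.0 * i + 1.0) / n_directions
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    theta = golden * i
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionScheme(bvalues=bvals, directions=directions)


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------


def _voxel_centers(config: PhantomConfig) -> np.ndarray:
    idx = np.indices(config.grid_shape).reshape(3, -1).T.astype(float)
    return voxel_to_world(config.affine, idx)


def make_roi_masks(config: PhantomConfig) -> tuple[BinaryMask, BinaryMask]:
    """Axis-aligned box ROIs around the bundle's two endpoints."""
    centers = _voxel_centers(config)
    shape = config.grid_shape
    masks = []
    for c in (config.seed_center_mm, config.target_center_mm):
        inside = np.all(np.abs(centers - np.asarray(c)) <= config.roi_half_size_mm, axis=1)
        data = inside.reshape(shape).astype(np.uint8)
        if data.sum() == 0:
            raise ValidationError(f"ROI box at {c} rasterises to an empty mask")
        masks.append(BinaryMask(data=data, affine=config.affine))
    seed, target = masks
    if np.any((seed.data > 0) & (target.data > 0)):
        raise ValidationError("seed and target ROI boxes overlap")
    return seed, target


def _center_curve(config: PhantomConfig, n: int = 200) -> np.ndarray:
    """Quadratic Bezier between the ROI centers, bowed by curvature_mm."""
    p0 = np.asarray(config.seed_center_mm, float)
    p2 = np.asarray(config.target_center_mm, float)
    chord = p2 - p0
    # bow the curve perpendicular to the chord, within the y-z (sagittal) plane
    perp = np.cross(chord, np.array([1.0, 0.0, 0.0]))
    norm = np.linalg.norm(perp)
    perp = perp / norm if norm > 0 else np.array([0.0, 1.0, 0.0])
    p1 = 0.5 * (p0 + p2) + config.curvature_mm * perp
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def make_aslant_bundle(config: PhantomConfig) -> Tractogram:
    """Bundle of parallel, jittered copies of the oblique center curve.

    Each streamline is the center curve shifted by a random offset drawn
    uniformly from the disk of radius ``bundle_radius_mm`` perpendicular to
    the seed-target chord, then resampled to 1 mm vertex spacing.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    curve = _center_curve(config)
    chord = np.asarray(config.target_center_mm, float) - np.asarray(config.seed_center_mm, float)
    chord = chord / np.linalg.norm(chord)
    # orthonormal basis of the plane perpendicular to the chord
    e1 = np.cross(chord, np.array([1.0, 0.0, 0.0]))
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(chord, np.array([0.0, 1.0, 0.0]))
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(chord, e1)
    streamlines = []
    for _ in range(config.n_streamlines):
        r = config.bundle_radius_mm * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        offset = r * (np.cos(phi) * e1 + np.sin(phi) * e2)
        streamlines.append(resample_streamline(curve + offset, 1.0))
    return Tractogram(streamlines=streamlines, frame_label="phantom RAS mm")


def make_tumor_mask(config: PhantomConfig) -> BinaryMask:
    """Rasterised sphere: voxels whose centers lie within the tumor radius."""
    centers = _voxel_centers(config)
    d = np.linalg.norm(centers - np.asarray(config.tumor_center_mm), axis=1)
    data = (d <= config.tumor_radius_mm).reshape(config.grid_shape).astype(np.uint8)
    if data.sum() == 0:
        raise ValidationError("tumor sphere rasterises to an empty mask")
    return BinaryMask(data=data, affine=config.affine)


def make_tensor_phantom(bundle: Tractogram, config: PhantomConfig) -> TensorField:
    """Prolate tensors along the bundle, isotropic elsewhere, oedema near tumor.

    Voxels within ``bundle_radius_mm`` of any bundle vertex get a prolate
    tensor with eigenvalues (lambda_parallel, lambda_perp, lambda_perp)
    aligned to the local mean tangent; all other voxels are isotropic with
    the same trace, so MD is constant everywhere outside the oedema shell.
    Voxels within ``tumor_radius + oedema_shell`` of the tumor center have
    their eigenvalues scaled by ``oedema_md_scale`` (raising MD, leaving FA
    unchanged).
    """
    if len(bundle) == 0:
        raise ValidationError("bundle is empty")
    lp, lt = config.lambda_parallel, config.lambda_perp
    iso = (lp + 2.0 * lt) / 3.0
    vertices = np.vstack(bundle.streamlines)
    tangents = np.vstack(
        [np.gradient(s, axis=0) for s in bundle.streamlines]
    )
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
    centers = _voxel_centers(config)
    tree = cKDTree(vertices)
    dist, nearest = tree.query(centers, k=1)
    in_bundle = dist <= config.bundle_radius_mm

    six = np.empty((centers.shape[0], 6))
    six[:] = matrix_to_six(iso * np.eye(3))
    if in_bundle.any():
        t = tangents[nearest[in_bundle]]
        outer = t[:, :, None] * t[:, None, :]
        D = lt * np.eye(3)[None] + (lp - lt) * outer
        six[in_bundle] = matrix_to_six(D)

    d_tumor = np.linalg.norm(centers - np.asarray(config.tumor_center_mm), axis=1)
    oedema = d_tumor <= config.tumor_radius_mm + config.oedema_shell_mm
    six[oedema] *= config.oedema_md_scale

    components = six.reshape(config.grid_shape + (6,))
    valid = np.ones(config.grid_shape, dtype=bool)
    return TensorField(components=components, valid=valid, affine=config.affine)


def simulate_dwi(
    field: TensorField, scheme: DiffusionScheme, config: PhantomConfig
) -> DWISeries:
    """Forward-simulate S = S0 exp(-b g' D g) with optional seeded noise.

    Gaussian noise with SD ``noise_sd * s0`` by default; ``noise_model=
    "rician"`` instead draws the magnitude of a complex signal with that
    noise per channel.  Signals are clipped at zero.
    """
    design = tensor_design_matrix(scheme)[:, 1:]  # (n_vol, 6) without intercept
    six = field.components.reshape(-1, 6)
    log_atten = six @ design.T
    signal = config.s0 * np.exp(log_atten)
    signal[~field.valid.ravel()] = 0.0
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed + 1)
        sd = config.noise_sd * config.s0
        if config.noise_model == "rician":
            re = signal + rng.normal(0.0, sd, signal.shape)
            im = rng.normal(0.0, sd, signal.shape)
            signal = np.hypot(re, im)
        else:
            signal = signal + rng.normal(0.0, sd, signal.shape)
    signal = np.maximum(signal, 0.0)
    data = signal.reshape(field.valid.shape + (len(scheme),))
    return DWISeries(data=data, scheme=scheme, affine=field.affine)


def phantom_with_tumor_gap(gap_mm: float, **overrides) -> PhantomConfig:
    """Config whose tumor surface sits ~``gap_mm`` from the bundle surface.

    The tumor center is placed laterally (+x) from the bundle's mid-curve
    point at ``bundle_radius + tumor_radius + gap_mm``, so the closest
    fiber-to-tumor-surface gap is approximately ``gap_mm``.
    """
    config = PhantomConfig(**overrides)
    mid = _center_curve(config)[100]
    offset = config.bundle_radius_mm + config.tumor_radius_mm + gap_mm
    config.tumor_center_mm = tuple(mid + np.array([offset, 0.0, 0.0]))
    return config


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: CohortConfig) -> tuple[CohortTable, dict]:
    """Simulate a cohort table plus the ground truth used to generate it.

    Per subject: hemisphere per the configured split; WHO grade, tumor
    volume, handedness, age, sex and education drawn from distributions
    matching a frontal-glioma surgical cohort; ipsilateral tract-tumor
    distance uniform in ``distance_bounds_mm``; tract MD coupled to
    proximity through an inverse-distance oedema proxy (plus noise) and
    tract FA coupled negatively to MD.  Cognitive z-scores are linear in
    distance and MD with the configured hemisphere-specific slopes plus
    covariate effects and Gaussian noise, generated on the oriented scale
    (lower = worse) and then stored raw, i.e. with the continuous
    performance and Stroop interference signs flipped back.

    Returns ``(cohort, truth)`` where ``truth`` records every planted
    parameter.  Deterministic given the config.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_right + config.n_left
    hemi = np.array(["right"] * config.n_right + ["left"] * config.n_left)

    age = np.clip(rng.normal(42.0, 13.0, n), 20.0, 67.0)
    sex = rng.choice(["male", "female"], n)
    education = rng.choice(["low", "middle", "high"], n, p=[0.125, 0.375, 0.5])
    grade = rng.choice([2, 3, 4], n, p=[49 / 72, 10 / 72, 13 / 72])
    volume = np.clip(rng.lognormal(np.log(35.0), 0.7, n), 1.0, 250.0)
    handedness = rng.choice(["right", "left"], n, p=[0.833, 0.167])

    lo, hi = config.distance_bounds_mm
    distance = rng.uniform(lo, hi, n)
    md_e3 = (
        config.md_base_e3
        + config.md_gain_e3 / (distance + config.md_floor_mm)
        + rng.normal(0.0, config.md_noise_e3, n)
    )
    md_e3 = np.clip(md_e3, 0.3, 3.0)
    fa = np.clip(0.40 - 0.5 * (md_e3 - config.md_base_e3) + rng.normal(0, 0.03, n), 0.05, 0.9)

    if config.effect_hemisphere == "both":
        affected = np.ones(n, dtype=bool)
    else:
        affected = hemi == config.effect_hemisphere

    mid_d = 0.5 * (lo + hi)
    mid_md_e4 = (config.md_base_e3 + config.md_gain_e3 / (mid_d + config.md_floor_mm)) * 10.0

    frame = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "affected_hemisphere": hemi,
            "tumor_grade": grade,
            "tumor_volume_cm3": np.round(volume, 2),
            "handedness": handedness,
            "education_level": education,
            "age_years": np.round(age, 1),
            "sex": sex,
            "min_mean_mm": distance,
            "mean_fa": fa,
            "mean_md": md_e3 * 1e-3,
        }
    )

    covariate_term = (
        config.grade_effect * (grade - 2)
        + config.volume_effect * volume
        + config.handedness_effect * (handedness == "left")
    )
    for test in COGNITIVE_TESTS:
        slope = config.slope_per_test.get(test, 0.0)
        md_slope = config.md_slope_per_test.get(test, 0.0)
        intercept = -(slope * mid_d + 0.0)  # center the distance effect
        z = (
            intercept
            + covariate_term
            + np.where(affected, slope * distance, 0.0)
            + np.where(affected, md_slope * (md_e3 * 10.0 - mid_md_e4), 0.0)
            + rng.normal(0.0, config.noise_sd, n)
        )
        if test in REVERSED_TESTS:
            z = -z  # stored raw; orient_scores flips these back
        frame[test] = z

    if config.missing_letter_fluency_fraction > 0:
        n_miss = int(round(config.missing_letter_fluency_fraction * n))
        miss = rng.choice(n, size=n_miss, replace=False)
        frame.loc[miss, "letter_fluency"] = np.nan

    truth = {
        "seed": config.seed,
        "slope_per_test": dict(config.slope_per_test),
        "md_slope_per_test": dict(config.md_slope_per_test),
        "effect_hemisphere": config.effect_hemisphere,
        "noise_sd": config.noise_sd,
        "covariates": {
            "grade_effect": config.grade_effect,
            "volume_effect": config.volume_effect,
            "handedness_effect": config.handedness_effect,
        },
        "distance_bounds_mm": list(config.distance_bounds_mm),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    cohort = CohortTable(
        frame=frame,
        provenance={"generator": "simulate_cohort", "seed": config.seed},
        scores_oriented=False,
    )
    return cohort, truth
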