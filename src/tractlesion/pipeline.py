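"""Orchestration: per-subject metrics, cohort analysis, simulation runs.

Ties the stages together into the per-subject -> cohort workflow: tract
selection and Min-mean distance, tensor fitting and tract-averaged FA/MD,
then the cohort correlation/BH screen and bootstrapped hierarchical
regressions.  Every run writes a JSON manifest (config, seed, versions) from
which it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .imaging import (
    BinaryMask,
    DWISeries,
    mask_volume_cm3,
    read_bvals_bvecs,
    read_nifti,
    read_nifti_4d,
    write_bvals_bvecs,
    write_nifti,
)
from .microstructure import fit_tensors, scalar_map, tract_mean_scalar
from .proximity import min_mean_distance
from .stats import (
    COGNITIVE_TESTS,
    TRACT_MEASURES,
    CohortTable,
    add_bh_flags,
    bootstrap_regression,
    correlation_screen,
    orient_scores,
    summarize_cohort,
)
from .streamlines import Tractogram, filter_by_seed_target, read_tck, tract_voxel_occupancy, write_tck
from .synthetic import (
    CohortConfig,
    PhantomConfig,
    default_scheme,
    make_aslant_bundle,
    make_roi_masks,
    make_tensor_phantom,
    make_tumor_mask,
    simulate_cohort,
    simulate_dwi,
)

__all__ = ["RunConfig", "subject_metrics", "run_cohort_analysis", "simulate_run"]

_AFFINE_TOL = 1e-4  # mm; inputs for one subject must share a world frame


@dataclass
class RunConfig:
    """One document configuring a pipeline run (YAML/JSON serialisable)."""

    mode: str = "full"  # simulate | metrics | analyze | full
    q: float = 0.1  # FDR level of the BH screen
    bootstrap_reps: int = 1000
    seed: int = 0
    out_dir: str = "tractlesion_out"
    resample_step_mm: float = 1.0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # input paths for metrics/analyze modes
    dwi_path: str | None = None
    bval_path: str | None = None
    bvec_path: str | None = None
    brain_mask_path: str | None = None
    tumor_mask_path: str | None = None
    seed_mask_path: str | None = None
    target_mask_path: str | None = None
    tck_path: str | None = None
    cohort_csv_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "metrics", "analyze", "full"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0 < self.q <= 1:
            raise ValidationError(f"q must be in (0, 1], got {self.q}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        phantom = PhantomConfig(**doc.pop("phantom", {}))
        cohort = CohortConfig(**doc.pop("cohort", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(phantom=phantom, cohort=cohort, **doc)


def _check_same_frame(*affines: np.ndarray) -> None:
    ref = np.asarray(affines[0])
    for a in affines[1:]:
        if np.max(np.abs(np.asarray(a) - ref)) > _AFFINE_TOL:
            raise ValidationError(
                "inputs do not share a world frame (affines differ beyond "
                f"{_AFFINE_TOL} mm); coregister them first"
            )


def subject_metrics(
    tractogram: Tractogram,
    tumor: BinaryMask,
    seed_mask: BinaryMask,
    target_mask: BinaryMask,
    dwi: DWISeries,
    brain: BinaryMask,
    *,
    tract_hemisphere: str,
    tumor_hemisphere: str,
    resample_step_mm: float = 1.0,
) -> dict:
    """Per-subject metric row for one tract.

    Min-mean is computed only when the tract and tumor are ipsilateral
    (otherwise reported missing, mirroring the n/a convention for
    contralateral combinations); FA/MD are always computed.  All inputs must
    share the subject's world frame.
    """
    _check_same_frame(tumor.affine, seed_mask.affine, target_mask.affine,
                      dwi.affine, brain.affine)
    tract = filter_by_seed_target(tractogram, seed_mask, target_mask)
    if len(tract) == 0:
        raise ValidationError("no streamlines connect the seed and target ROIs")
    row: dict = {
        "tract_hemisphere": tract_hemisphere,
        "n_streamlines": len(tract),
        "tumor_volume_cm3": mask_volume_cm3(tumor),
    }
    if tract_hemisphere == tumor_hemisphere:
        result = min_mean_distance(tract, tumor, resample_step=resample_step_mm)
        row["min_mean_mm"] = result.min_mean
    else:
        row["min_mean_mm"] = np.nan
    field = fit_tensors(dwi, brain)
    fa_map = scalar_map(field, "FA")
    md_map = scalar_map(field, "MD")
    occupancy = tract_voxel_occupancy(tract, fa_map)
    row["mean_fa"], row["n_tract_voxels"] = tract_mean_scalar(fa_map, occupancy)
    row["mean_md"], _ = tract_mean_scalar(md_map, occupancy)
    return row


def run_cohort_analysis(config: RunConfig, cohort: CohortTable) -> dict:
    """Full cohort statistics; writes CSV tables and a manifest to out_dir.

    Produces stratified descriptives, the Spearman screen with per-family BH
    flags at level q, and one bootstrapped hierarchical regression per
    (cognitive test x tract measure x hemisphere).  Returns the tables in a
    dict; CSVs land in ``config.out_dir``.
    """
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    if not cohort.scores_oriented:
        cohort = orient_scores(cohort)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    descriptives = summarize_cohort(cohort)
    screen = add_bh_flags(correlation_screen(cohort), q=config.q)

    reg_rows = []
    rng = np.random.default_rng(config.seed)
    for measure in TRACT_MEASURES:
        for hemi in ("right", "left"):
            for test in COGNITIVE_TESTS:
                boot_seed = int(rng.integers(0, 2**31 - 1))
                try:
                    res = bootstrap_regression(
                        cohort, test, added=measure,
                        reps=config.bootstrap_reps, seed=boot_seed,
                        hemisphere=hemi,
                    )
                except ValidationError:
                    continue
                reg_rows.append(
                    {
                        "outcome": test,
                        "measure": measure,
                        "hemisphere": hemi,
                        "n": res.n,
                        "base_f": res.base_f,
                        "base_df1": res.base_df[0],
                        "base_df2": res.base_df[1],
                        "base_p": res.base_p,
                        "r2_base": res.r2_base,
                        "B": res.b,
                        "ci_low": res.ci_lower,
                        "ci_high": res.ci_upper,
                        "boot_p": res.boot_p,
                        "significant": res.significant,
                        "f_change": res.f_change,
                        "df1": res.f_change_df[0],
                        "df2": res.f_change_df[1],
                        "f_change_p": res.f_change_p,
                        "r2_full": res.r2_full,
                    }
                )
    regressions = pd.DataFrame(reg_rows)

    float_fmt = "%.6g"
    descriptives.to_csv(out / "descriptives.csv", index=False, float_format=float_fmt)
    screen.to_csv(out / "correlations.csv", index=False, float_format=float_fmt)
    regressions.to_csv(out / "regressions.csv", index=False, float_format=float_fmt)
    manifest = {
        "tool": "tractlesion",
        "version": __version__,
        "seed": config.seed,
        "q": config.q,
        "bootstrap_reps": config.bootstrap_reps,
        "n_subjects": len(cohort),
        "cohort_provenance": cohort.provenance,
        "numpy_version": np.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "descriptives": descriptives,
        "correlations": screen,
        "regressions": regressions,
        "manifest": manifest,
    }


def simulate_run(config: RunConfig) -> dict:
    """Generate the full synthetic dataset on disk.

    Writes the phantom (DWI NIfTI + bval/bvec, brain/tumor/ROI masks, bundle
    TCK), the simulated cohort CSV, and a truth JSON with every planted
    parameter.  All randomness is derived from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    phantom = dataclasses.replace(config.phantom, seed=int(stage_seeds[0]))
    cohort_cfg = dataclasses.replace(config.cohort, seed=int(stage_seeds[1]))

    scheme = default_scheme()
    seed_mask, target_mask = make_roi_masks(phantom)
    bundle = make_aslant_bundle(phantom)
    tumor = make_tumor_mask(phantom)
    tensors = make_tensor_phantom(bundle, phantom)
    dwi = simulate_dwi(tensors, scheme, phantom)
    brain = BinaryMask(data=np.ones(phantom.grid_shape, dtype=np.uint8),
                       affine=phantom.affine)

    write_nifti(dwi, out / "dwi.nii.gz")
    write_bvals_bvecs(scheme, out / "dwi.bval", out / "dwi.bvec")
    for name, mask in [("brain", brain), ("tumor", tumor),
                       ("roi_seed", seed_mask), ("roi_target", target_mask)]:
        write_nifti(mask, out / f"{name}_mask.nii.gz")
    write_tck(bundle, out / "bundle.tck")

    cohort, truth = simulate_cohort(cohort_cfg)
    cohort.to_csv(out / "cohort.csv")
    truth["phantom"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(phantom).items()
    }
    truth["root_seed"] = config.seed
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return {
        "out_dir": out,
        "scheme": scheme,
        "bundle": bundle,
        "tumor": tumor,
        "seed_mask": seed_mask,
        "target_mask": target_mask,
        "dwi": dwi,
        "brain": brain,
        "cohort": cohort,
        "truth": truth,
    }


def load_subject_inputs(config: RunConfig) -> dict:
    """Read the per-subject files named in a metrics-mode config."""
    required = {
        "dwi_path": config.dwi_path,
        "bval_path": config.bval_path,
        "bvec_path": config.bvec_path,
        "brain_mask_path": config.brain_mask_path,
        "tumor_mask_path": config.tumor_mask_path,
        "seed_mask_path": config.seed_mask_path,
        "target_mask_path": config.target_mask_path,
        "tck_path": config.tck_path,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ValidationError(f"metrics mode needs paths: {missing}")
    scheme = read_bvals_bvecs(config.bval_path, config.bvec_path)

    def as_mask(path):
        v = read_nifti(path)
        return BinaryMask(data=(v.data > 0.5).astype(np.uint8), affine=v.affine)

    return {
        "dwi": read_nifti_4d(config.dwi_path, scheme),
        "brain": as_mask(config.brain_mask_path),
        "tumor": as_mask(config.tumor_mask_path),
        "seed_mask": as_mask(config.seed_mask_path),
        "target_mask": as_mask(config.target_mask_path),
        "tractogram": read_tck(config.tck_path),
    }
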