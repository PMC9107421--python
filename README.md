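# tractlesion

Quantitative tractography lesion-symptom analysis for brain-tumor cohorts.

When a glioma grows near a white-matter pathway such as the frontal aslant
tract (FAT), how close it comes — and how much it disturbs the tract's
microstructure — may carry information about a patient's cognitive
functioning before surgery. `tractlesion` turns a subject's tractogram,
tumor segmentation and diffusion-weighted MRI into three scalar tract
measures and relates them to cognitive test z-scores across a cohort. It is
aimed at researchers running tractometry studies who already have
coregistered tractograms (TCK) and masks (NIfTI) per subject, and it ships
a synthetic phantom/cohort generator so the entire pipeline is testable
without patient data.

## The measures and the statistics

**Mean minimal distance (Min-mean).** For each fiber *f* of a tract with
vertices *v*, and tumor voxel centers *c*,

    d(f) = 0                      if some vertex lies inside the tumor mask
    d(f) = min_{v,c} ||v - c||    otherwise (exact nearest-neighbour search)

    Min-mean = (1/N) * sum_f d(f)      [mm, over all N fibers]

**Tract-averaged FA and MD.** A single diffusion tensor D is fitted per
voxel by least squares on log S(g) = log S0 − b gᵀDg; from its eigenvalues
λ1 ≥ λ2 ≥ λ3 (clamped at 0),

    FA = sqrt(1/2) * sqrt(((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / (λ1²+λ2²+λ3²))
    MD = (λ1 + λ2 + λ3) / 3

averaged without weights over the unique voxels the tract occupies.

**Cohort statistics.** Scores are oriented so lower z = worse; each
(measure, hemisphere, test) cell gets a Spearman rho/p with pairwise
deletion; each six-test column is corrected by the Benjamini-Hochberg
step-up rule at FDR q = 0.1; Cook's distances flag outliers (report-only);
and each outcome is modelled hierarchically — base covariates (tumor grade,
tumor volume, handedness) versus base + tract measure — with F-change,
ΔR², and a case-resampled percentile-bootstrap 95% CI (1000 resamples) on
the added slope.

## Worked example

Place a phantom tumor ~1 mm from a synthetic frontal bundle, measure it,
and run the regression on a simulated cohort:

```python
import numpy as np
import tractlesion as tl

cfg = tl.phantom_with_tumor_gap(1.0, seed=42)
bundle = tl.make_aslant_bundle(cfg)
tumor = tl.make_tumor_mask(cfg)
res = tl.min_mean_distance(bundle, tumor)
print(f"Min-mean: {res.min_mean:.2f} mm over {res.n_fibers} fibers")

field = tl.make_tensor_phantom(bundle, cfg)
dwi = tl.simulate_dwi(field, tl.default_scheme(), cfg)
brain = tl.BinaryMask(data=np.ones(cfg.grid_shape), affine=cfg.affine)
fit = tl.fit_tensors(dwi, brain)
fa, md = tl.scalar_map(fit, "FA"), tl.scalar_map(fit, "MD")
occ = tl.tract_voxel_occupancy(bundle, fa)
mean_fa, n = tl.tract_mean_scalar(fa, occ)
mean_md, _ = tl.tract_mean_scalar(md, occ)
print(f"tract FA: {mean_fa:.3f}   tract MD: {mean_md*1e3:.2f} x1e-3 mm^2/s   ({n} voxels)")

cohort, truth = tl.simulate_cohort(tl.CohortConfig(seed=42))
oriented = tl.orient_scores(cohort)
reg = tl.bootstrap_regression(oriented, "shifting_attention",
                              reps=1000, seed=42, hemisphere="right")
print(f"shifting attention ~ base + Min-mean (right, n={reg.n}):")
print(f"  B = {reg.b:.3f} z/mm, 95% CI ({reg.ci_lower:.3f}, {reg.ci_upper:.3f}), "
      f"F-change = {reg.f_change:.2f} {reg.f_change_df}, "
      f"R2 {reg.r2_base:.3f} -> {reg.r2_full:.3f}")
```

prints

```
Min-mean: 6.68 mm over 50 fibers
tract FA: 0.770   tract MD: 0.71 x1e-3 mm^2/s   (491 voxels)
shifting attention ~ base + Min-mean (right, n=32):
  B = 0.070 z/mm, 95% CI (0.033, 0.103), F-change = 14.68 (1, 27), R2 0.235 -> 0.504
```

The tumor sits a millimetre from the bundle surface, so the fibers' minimal
distances average 6.7 mm (distances are measured to tumor voxel *centers*,
and fibers are spread across the 4 mm bundle radius). Tract FA ≈ 0.77 is
the analytic value for the planted prolate tensors. In the simulated
cohort, one extra millimetre of distance predicts a 0.070 z-unit better
shifting-attention score, the CI excluding zero (the generator planted
0.061 z/mm plus a proximity-coupled MD effect).

A command-line interface wraps the same stages:

```sh
tractlesion simulate --seed 7 --out sim/        # phantom + cohort + truth JSON
tractlesion analyze --cohort sim/cohort.csv --out results/
tractlesion full --seed 7 --out run/            # both, end to end
```

## Layout

| Module | Contents |
| --- | --- |
| `tractlesion.imaging` | volumes, affines, masks, NIfTI + bval/bvec I/O |
| `tractlesion.streamlines` | TCK I/O, ROI selection, occupancy, resampling |
| `tractlesion.proximity` | per-fiber minimal distance, Min-mean |
| `tractlesion.microstructure` | tensor fit, FA/MD, tract averaging |
| `tractlesion.stats` | orientation, descriptives, Spearman/BH, bootstrap regression |
| `tractlesion.synthetic` | phantom + cohort generators |
| `tractlesion.pipeline`, `tractlesion.cli` | orchestration, manifests, CLI |

See `docs/methods.md` for conventions, model assumptions, parameter
defaults and known limitations.
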