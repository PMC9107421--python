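# Methods

## Problem and scope

`tractlesion` implements a quantitative tractography lesion-symptom analysis
for brain-tumor cohorts. The pipeline takes, per subject, a streamline
reconstruction of a white-matter tract (here the frontal aslant tract, FAT,
connecting the pre-SMA/SMA to the pars opercularis/triangularis), a binary
tumor segmentation, and a diffusion-weighted series, and reduces them to
three scalar tract measures:

* **Min-mean** — the mean, over all fibers of the tract, of each fiber's
  shortest Euclidean distance (mm) to the nearest tumor voxel;
* **mean FA** and **mean MD** — tract-averaged fractional anisotropy and
  mean diffusivity from a per-voxel single-tensor fit.

At cohort level these measures are relative to six cognitive test z-scores
through a Spearman correlation screen with Benjamini-Hochberg FDR control
and a bootstrapped hierarchical linear regression. Fiber tracking itself,
atlas registration and tumor segmentation are out of scope: tractograms and
masks are inputs (or phantom-generated), assumed coregistered to one world
frame per subject.

## Geometry conventions

A voxel index (i, j, k) names the voxel center; the voxel occupies the
half-open cube [i-0.5, i+0.5) per axis in continuous index space. The world
frame is RAS mm as given by the NIfTI affine (sform when valid, else qform);
no reorientation or resampling between grids is performed. Streamlines are
polylines of world-space points; TCK I/O uses the MRtrix dialect
(Float32LE, NaN-triplet separators, Inf-triplet terminator).

## Min-mean distance

The tumor is represented by the world-space centers of its set voxels. A
fiber's distance is 0 if any of its vertices falls inside a tumor voxel
(infiltration convention — without it an infiltrated tract would be floored
at half-voxel distances); otherwise it is the exact minimum vertex-to-center
distance, found with a k-d tree (brute force below ~2x10^4 vertex-voxel
pairs; both paths are exact and tested for equality to 1e-9 mm).

Distances are evaluated at vertices, not along segments. Fibers are first
resampled so vertex spacing is at most 1 mm (configurable): each original
segment is subdivided into equal pieces, so the polyline, its endpoints and
its arc length are unchanged. The vertex discretisation error of the
distance is then bounded by half the spacing (0.5 mm), well below the 2 mm
voxel size. Measuring to voxel centers rather than corners or the mask
surface shifts distances by at most half a voxel diagonal (~1.73 mm at 2 mm
isotropic); the convention is fixed and documented rather than configurable.

Using all tumor voxels rather than only surface voxels gives identical
results (the nearest set voxel is necessarily on the surface). Distance is
computed only for ipsilateral tract-tumor pairs; contralateral combinations
are reported missing.

## Tensor fit and tract averaging

The single-tensor model log S(g) = log S0 - b g'Dg is fitted per voxel by
ordinary least squares on log-signals, all b=0 volumes entering as rows with
zero diffusion weighting (no pre-averaging). A one-step weighted variant
(weights = squared predicted signals) is available. Non-positive signals are
clamped to a small epsilon before the log and the voxel flagged. Eigenvalues
are clamped at zero before FA/MD so FA stays in [0, 1] under noise.

FA = sqrt(1/2) sqrt(((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / (l1^2+l2^2+l3^2)),
MD = (l1+l2+l3)/3. Tract averaging is an unweighted mean over the *unique*
voxels containing at least one streamline vertex (occupancy is vertex-based;
with 1 mm resampling on a 2 mm grid this coincides with segment
rasterisation). A per-vertex visitation-weighted mean is available behind
the `weights` argument but is not the default, which follows the
voxel-unique reading of per-voxel tract averaging.

## Cohort statistics

* **Orientation.** Continuous performance and Stroop interference z-scores
  are sign-flipped so lower always means worse; a provenance flag makes the
  operation non-repeatable.
* **Descriptives.** Median with Q1/Q3 as medians of the lower/upper halves
  (central value excluded for odd n) for distance and tumor volume; mean
  (SD) for FA and MD, MD also on the x1e-3 mm^2/s scale.
* **Spearman screen.** Midrank-based rho with a t-approximation p (n-2 df),
  pairwise-complete per (measure, hemisphere, test) cell. Cells with < 3
  pairs or zero rank variance are flagged not-computed.
* **BH FDR.** Step-up rule at q = 0.1 by default. The family is one
  (measure, hemisphere) column of six tests; because the family definition
  is an analysis choice, `add_bh_flags` accepts any grouping columns.
* **Cook screening.** Cook's distances from the OLS fit, flags at D > 4/n,
  report-only — observations are never auto-removed.
* **Hierarchical regression.** Base model: tumor grade (ordinal 2/3/4 by
  default; dummy coding optional), tumor volume (cm^3), handedness
  (binary). Full model adds one tract measure on its native scale. The
  increment is summarised by F-change on (k_full-k_base, n-k_full-1) df and
  delta-R^2. Confidence intervals are percentile bootstrap over 1000
  (default) case resamples of subjects; significance = the 95% CI excludes
  zero, and a percentile bootstrap p (smallest two-sided level at which the
  CI excludes zero, floored at 1/reps) is reported alongside.
* **Degenerate resamples.** A resample is redrawn (and counted; > 10% is an
  error) only when the added measure becomes collinear with the base
  covariates, making its slope inestimable. Resamples where only a nuisance
  covariate degenerates — e.g. a resample of a 32-subject stratum that
  happens to contain no left-handed subjects — are kept, since the added
  slope is still the unique least-squares value there and discarding such
  draws would bias the bootstrap distribution whenever a categorical
  covariate has a rare level.

## Synthetic data

The phantom emulates the acquisition and geometry the analysis assumes:
a 2 mm isotropic grid, an oblique frontal bundle of 50 parallel jittered
streamlines (quadratic Bezier center curve between two box ROIs, offsets
uniform in a 4 mm-radius disk), a spherical tumor at a controlled distance
with a 4 mm oedema shell, prolate tensors (1.5, 0.3, 0.3)x10^-3 mm^2/s
along the bundle (FA ~ 0.77) over an isotropic background of equal trace,
and a 56-volume scheme (6 b=0 + 50 Fibonacci-lattice directions at
b=1500 s/mm^2). Signals follow S = S0 exp(-b g'Dg) with optional Gaussian
(default) or Rician noise. Oedema scales eigenvalues by 1.4, raising MD and
leaving FA unchanged. Tumor gaps of ~1 mm and ~18 mm from the bundle surface
yield Min-mean values near 5 and 23 mm, the two reference configurations
the pipeline is checked against.

The cohort generator draws 32 right- and 40 left-hemisphere subjects with
covariates matching a frontal-glioma surgical population (WHO grades
2/3/4 at 68/14/18%, log-normal tumor volume with ~35 cm^3 median, 17%
left-handedness), an ipsilateral distance uniform on 1-25 mm, tract MD
coupled to proximity by an inverse-distance oedema proxy with a floor
(MD_e3 = 0.78 + 1/(d+3) + noise), and FA coupled negatively to MD.
Cognitive z-scores are linear in distance (default slope 0.061 z/mm on
shifting attention) and MD (default -0.302 z per 1e-4 mm^2/s on shifting
attention), planted in right-hemisphere subjects only, plus small covariate
effects and Gaussian residual noise of SD 0.9 — chosen so the full model's
R^2 sits near 0.2, the scale of the effect sizes this design targets.
Scores are generated on the oriented scale and stored raw (the two reversed
tests flipped back), so the pipeline's orientation step is exercised end to
end. Letter fluency is masked at a 30% fraction to reproduce the reduced-n
pattern of that test.

What the generator deliberately omits: cortical anatomy, crossing bundles,
partial-volume effects, susceptibility/eddy artifacts and non-linear
score-distance relationships. Passing tests therefore demonstrate the
correctness and calibration of the computations, not robustness to the
acquisition artifacts of real clinical data.

## Statistical power at the default conditions

At the default planted slope (0.061 z/mm) and residual noise (R^2 ~ 0.2),
Spearman power within a six-test BH family at n=32 is roughly 70% — a
right-hemisphere effect is detected in about 7 of 10 simulated cohorts,
while left-hemisphere (null) families flag at the nominal ~10% FDR level.
The right/left dissociation is therefore reproducible as a direction and a
calibration property, not as a near-certain event in any single cohort;
this mirrors the small-sample power limits typical of single-center
neurosurgical samples.

## Numerical choices and problem sizes

* Exact nearest-neighbour search; k-d tree and brute force must agree to
  1e-9 mm (tested on random instances).
* Tensor fits solve all voxels with one pseudoinverse; the default phantom
  grid is 40x44x36 voxels (closure tests run in seconds).
* Calibration studies use 500 null replicates, and 200 recovery replicates
  with 500 bootstrap resamples each; single analyses default to 1000
  resamples.
* All generators and analyses are deterministic given their seed; pipeline
  runs derive per-stage seeds from one root seed and record them in the run
  manifest, from which any run is reproducible byte-for-byte.

## Known limitations

* Vertex-based occupancy and distance depend (boundedly) on the resampling
  step; segment-exact variants are not implemented.
* The single-tensor model is the only diffusion model; no multi-shell or
  fiber-orientation-distribution support.
* The bootstrap p-value is the percentile-CI inversion, one of several
  reasonable constructions.
* The cohort generator's covariate distributions are plausible but not
  fitted to any dataset; absolute descriptives from synthetic cohorts are
  illustrative only.
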