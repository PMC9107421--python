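"""Cohort-level lesion-symptom statistics.

Implements the analysis chain applied to per-subject tract metrics and
cognitive z-scores: score orientation (so lower always means worse),
stratified descriptives, a Spearman correlation screen with per-family
Benjamini-Hochberg FDR control, Cook's-distance outlier screening, and
hierarchical linear regression (base covariates vs base + tract measure)
with case-resampled percentile-bootstrap confidence intervals and an
F-change / delta-R^2 comparison.

The cohort lives in a :class:`CohortTable`: a pandas DataFrame with one row
per subject plus provenance metadata.  Missing values are empty cells;
correlations use pairwise deletion, regressions complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import RegressionError, ValidationError

__all__ = [
    "COGNITIVE_TESTS",
    "REVERSED_TESTS",
    "TRACT_MEASURES",
    "CohortTable",
    "CorrelationResult",
    "BHOutcome",
    "RegressionComparison",
    "orient_scores",
    "summarize_cohort",
    "spearman",
    "correlation_screen",
    "benjamini_hochberg",
    "add_bh_flags",
    "cook_screen",
    "ols_fit",
    "f_change",
    "bootstrap_regression",
]

#: The six cognitive tests, as z-score columns of the cohort table.
COGNITIVE_TESTS = (
    "finger_tapping",
    "symbol_digit_coding",
    "shifting_attention",
    "continuous_performance",
    "stroop_interference",
    "letter_fluency",
)

#: Tests whose raw z-scores increase with worse performance; orientation
#: multiplies these by -1 so that for all tests lower = worse.
REVERSED_TESTS = ("continuous_performance", "stroop_interference")

#: Per-subject tract measures relating to the ipsilateral tract.
TRACT_MEASURES = ("min_mean_mm", "mean_md", "mean_fa")

#: Default base covariates of the hierarchical regression.
BASE_COVARIATES = ("tumor_grade", "tumor_volume_cm3", "handedness")


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """One row per subject; ``provenance`` records seed or file source."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    scores_oriented: bool = False

    def __post_init__(self) -> None:
        if "subject_id" not in self.frame.columns:
            raise ValidationError("cohort table needs a 'subject_id' column")
        if self.frame["subject_id"].duplicated().any():
            raise ValidationError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path, *, scores_oriented: bool = False) -> "CohortTable":
        frame = pd.read_csv(path)
        return cls(frame=frame, provenance={"source": str(path)},
                   scores_oriented=scores_oriented)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def orient_scores(cohort: CohortTable) -> CohortTable:
    """Flip the sign of the reversed tests so lower z always means worse.

    Idempotency is guarded: orienting an already-oriented cohort is an error.
    """
    if cohort.scores_oriented:
        raise ValidationError("scores are already oriented; refusing to flip twice")
    frame = cohort.frame.copy()
    for test in REVERSED_TESTS:
        if test in frame.columns:
            frame[test] = -frame[test]
    return CohortTable(
        frame=frame,
        provenance={**cohort.provenance, "scores_oriented": True},
        scores_oriented=True,
    )


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


def _half_median_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median with Q1/Q3 as medians of the lower/upper halves.

    For odd n the central value is excluded from both halves; a single value
    is its own median and both quartiles.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    med = float(np.median(v))
    if n == 1:
        return med, med, med
    half = n // 2
    lower, upper = v[:half], v[n - half:]
    return med, float(np.median(lower)), float(np.median(upper))


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Stratified descriptives: distance median (Q1; Q3), FA/MD mean (SD).

    One row per affected-hemisphere stratum.  MD is additionally reported on
    the x1e-3 mm^2/s scale (``mean_md_e3``).  Empty strata are skipped.
    """
    rows = []
    for hemi in ("right", "left"):
        sub = cohort.frame[cohort.frame["affected_hemisphere"] == hemi]
        if len(sub) == 0:
            continue
        row: dict = {"hemisphere": hemi, "n": len(sub)}
        d = sub["min_mean_mm"].dropna().to_numpy()
        if len(d):
            med, q1, q3 = _half_median_quartiles(d)
            row.update(min_mean_median=med, min_mean_q1=q1, min_mean_q3=q3)
        v = sub.get("tumor_volume_cm3", pd.Series(dtype=float)).dropna().to_numpy()
        if len(v):
            med, q1, q3 = _half_median_quartiles(v)
            row.update(tumor_volume_median=med, tumor_volume_q1=q1, tumor_volume_q3=q3)
        for col in ("mean_fa", "mean_md"):
            vals = sub.get(col, pd.Series(dtype=float)).dropna().to_numpy()
            if len(vals):
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        if "mean_md_mean" in row:
            row["mean_md_mean_e3"] = row["mean_md_mean"] * 1e3
            row["mean_md_sd_e3"] = row["mean_md_sd"] * 1e3
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman screen with BH FDR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    test_name: str
    measure_name: str
    n: int
    rho: float
    p_value: float


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with midranks on ties.

    Pairs with a missing member are dropped; p comes from the t-approximation
    with n-2 degrees of freedom.  Zero rank variance is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >=3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("zero variance: Spearman correlation undefined")
    rho, p = scipy.stats.spearmanr(x, y)
    if not np.isfinite(rho):
        raise ValidationError("Spearman correlation undefined for these data")
    return CorrelationResult(test_name="", measure_name="", n=n,
                             rho=float(rho), p_value=float(p))


def correlation_screen(
    cohort: CohortTable,
    measures: Sequence[str] = TRACT_MEASURES,
    tests: Sequence[str] = COGNITIVE_TESTS,
) -> pd.DataFrame:
    """Spearman rho/p for every (measure, hemisphere stratum, test) cell.

    Requires oriented scores.  Uses pairwise-complete observations per cell;
    cells with fewer than 3 complete pairs or zero variance are flagged
    ``computed = False``.
    """
    if not cohort.scores_oriented:
        raise ValidationError("orient_scores must be applied before the screen")
    rows = []
    for measure in measures:
        for hemi in ("right", "left"):
            sub = cohort.frame[cohort.frame["affected_hemisphere"] == hemi]
            for test in tests:
                row = {"measure": measure, "hemisphere": hemi, "test": test,
                       "n": 0, "rho": np.nan, "p": np.nan, "computed": False}
                if measure in sub.columns and test in sub.columns:
                    try:
                        res = spearman(sub[measure], sub[test])
                        row.update(n=res.n, rho=res.rho, p=res.p_value, computed=True)
                    except ValidationError:
                        pass
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BHOutcome:
    """Benjamini-Hochberg step-up outcome for one family of p-values."""

    family: str
    p_values: np.ndarray
    q: float
    significant_flags: np.ndarray

    @property
    def n_significant(self) -> int:
        return int(self.significant_flags.sum())


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.1,
                       family: str = "") -> BHOutcome:
    """BH step-up rule at FDR level q.

    Sort ascending, find the largest k with p_(k) <= k q / m, and flag the k
    smallest p-values.  Flags are returned aligned to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if not (0 < q <= 1):
        raise ValidationError(f"q must be in (0, 1], got {q}")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return BHOutcome(family=family, p_values=p, q=q,
                     significant_flags=np.asarray(reject, dtype=bool))


def add_bh_flags(
    screen: pd.DataFrame,
    q: float = 0.1,
    family_cols: Sequence[str] = ("measure", "hemisphere"),
) -> pd.DataFrame:
    """Attach per-family BH flags to a correlation-screen table.

    The default family is one (measure, hemisphere) column of the screen,
    i.e. the six cognitive tests of one table column.  Other groupings can be
    requested via ``family_cols`` since the family definition is an analysis
    choice, not a fact of the data.
    """
    out = screen.copy()
    out["bh_flag"] = False
    out["bh_q"] = q
    for _, idx in out.groupby(list(family_cols)).groups.items():
        sub = out.loc[idx]
        ok = sub["computed"] & np.isfinite(sub["p"])
        if not ok.any():
            continue
        res = benjamini_hochberg(sub.loc[ok, "p"].to_numpy(), q=q)
        out.loc[sub.index[ok], "bh_flag"] = res.significant_flags
    return out


# ---------------------------------------------------------------------------
# Regression machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OLSFit:
    coefficients: np.ndarray  # intercept first
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float


def _design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    return X


def ols_fit(X: np.ndarray, y: Sequence[float]) -> OLSFit:
    """Ordinary least squares with intercept; overall F on (k, n-k-1) df."""
    X = _design(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise RegressionError(f"need n > parameters + 1, got n={n}, k={k}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RegressionError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    return OLSFit(
        coefficients=np.asarray(fit.params),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
    )


def cook_screen(
    X: np.ndarray, y: Sequence[float], threshold: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cook's distances from the OLS fit and flags where D > threshold.

    Default threshold 4/n.  Flags are report-only: no observation is removed.
    """
    X = _design(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if threshold is None:
        threshold = 4.0 / n
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1] or n <= design.shape[1]:
        raise RegressionError("cannot compute Cook's distances: degenerate design")
    fit = sm.OLS(y, design).fit()
    d = np.asarray(OLSInfluence(fit).cooks_distance[0])
    return d, d > threshold


def f_change(
    base_r2: float, full_r2: float, n: int, k_base: int, k_full: int
) -> tuple[float, tuple[int, int], float]:
    """Hierarchical-regression F for the R^2 increment of added predictors.

    F = ((R2_full - R2_base) / (k_full - k_base)) / ((1 - R2_full) / (n - k_full - 1)),
    on (k_full - k_base, n - k_full - 1) degrees of freedom.
    """
    if k_full <= k_base:
        raise ValidationError("k_full must exceed k_base")
    if n <= k_full + 1:
        raise ValidationError(f"need n > k_full + 1, got n={n}, k_full={k_full}")
    if full_r2 < base_r2 - 1e-12:
        raise ValidationError("full-model R^2 cannot be below the base model's")
    df1, df2 = k_full - k_base, n - k_full - 1
    num = max(full_r2 - base_r2, 0.0) / df1
    den = (1.0 - full_r2) / df2
    f = num / den if den > 0 else np.inf
    p = float(scipy.stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), (df1, df2), p


@dataclass(frozen=True)
class RegressionComparison:
    """Base vs base+measure hierarchical regression with bootstrap CI."""

    outcome: str
    added: str
    n: int
    base_f: float
    base_df: tuple[int, int]
    base_p: float
    r2_base: float
    b: float  # slope of the added predictor, native scale
    ci_lower: float
    ci_upper: float
    boot_p: float
    significant: bool
    f_change: float
    f_change_df: tuple[int, int]
    f_change_p: float
    r2_full: float
    n_redrawn: int
    seed: int
    reps: int


def _encode_covariates(frame: pd.DataFrame, covariates: Sequence[str],
                       dummy_grade: bool = False) -> np.ndarray:
    """Numeric design columns: handedness/sex as 0-1 indicators, WHO grade
    ordinal (2/3/4) by default or dummy-coded on request."""
    cols = []
    for cov in covariates:
        v = frame[cov]
        if cov == "handedness":
            cols.append((v == "left").astype(float).to_numpy())
        elif cov == "sex":
            cols.append((v == "female").astype(float).to_numpy())
        elif cov == "tumor_grade" and dummy_grade:
            for g in (3, 4):
                cols.append((v == g).astype(float).to_numpy())
        else:
            cols.append(v.astype(float).to_numpy())
    return np.column_stack(cols)


def bootstrap_regression(
    cohort: CohortTable,
    outcome: str,
    base: Sequence[str] = BASE_COVARIATES,
    added: str = "min_mean_mm",
    reps: int = 1000,
    seed: int = 0,
    *,
    hemisphere: str | None = None,
    dummy_grade: bool = False,
    ci_level: float = 95.0,
) -> RegressionComparison:
    """Hierarchical regression with case-resampled percentile-bootstrap CI.

    The base model regresses the outcome z-score on the base covariates; the
    full model adds the tract measure.  The point estimate B is the
    full-model slope of the added measure on the observed complete cases;
    the CI comes from ``reps`` case resamples (subjects drawn with
    replacement) refitted with the full model, taking the 2.5/97.5 empirical
    percentiles.  Significance = CI excludes zero; a percentile bootstrap
    p-value (smallest two-sided level at which the CI excludes zero) is
    reported alongside.

    A resample is degenerate when the added measure becomes collinear with
    the base covariates, leaving its slope inestimable; such resamples are
    redrawn and counted, and more than 10% redraws is an error.  A resample
    in which only a nuisance covariate degenerates (e.g. every drawn subject
    is right-handed, so the handedness dummy is constant) is kept: the added
    slope is then still the unique least-squares value, and discarding such
    draws would bias the bootstrap distribution against small strata.
    """
    if reps < 100:
        raise ValidationError("reps must be at least 100")
    frame = cohort.frame
    if hemisphere is not None:
        frame = frame[frame["affected_hemisphere"] == hemisphere]
    need = [outcome, added, *base]
    cc = frame.dropna(subset=[c for c in need if c in frame.columns])
    missing = [c for c in need if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort lacks columns {missing}")
    n = len(cc)
    X_base = _encode_covariates(cc, base, dummy_grade=dummy_grade)
    # a covariate constant within this stratum (e.g. no left-handed subjects)
    # carries no information; drop it rather than fail on a constant column
    informative = X_base.std(axis=0) > 0
    X_base = X_base[:, informative]
    if X_base.shape[1] == 0:
        raise RegressionError("all base covariates are constant in this subset")
    x_added = cc[added].astype(float).to_numpy()
    if any(np.allclose(x_added, X_base[:, j]) for j in range(X_base.shape[1])):
        raise RegressionError(f"added predictor {added!r} duplicates a base covariate")
    X_full = np.column_stack([X_base, x_added])
    y = cc[outcome].astype(float).to_numpy()
    k_base, k_full = X_base.shape[1], X_full.shape[1]
    if n <= k_full + 1:
        raise ValidationError(f"complete-case n={n} too small for k_full={k_full}")

    base_fit = ols_fit(X_base, y)
    full_fit = ols_fit(X_full, y)
    b_hat = float(full_fit.coefficients[-1])
    fch, fch_df, fch_p = f_change(base_fit.r_squared, full_fit.r_squared,
                                  n, k_base, k_full)

    rng = np.random.default_rng(seed)
    design_full = np.column_stack([np.ones(n), X_full])
    boots = np.empty(reps)
    n_redrawn = 0
    max_redraws = int(np.ceil(0.10 * reps))
    i = 0
    while i < reps:
        rows = rng.integers(0, n, size=n)
        d = design_full[rows]
        coef, _, rank, _ = np.linalg.lstsq(d, y[rows], rcond=None)
        if rank < d.shape[1]:
            # added slope inestimable only if its column lies in the span of
            # the base columns of this resample
            if np.linalg.matrix_rank(d[:, :-1]) == rank:
                n_redrawn += 1
                if n_redrawn > max_redraws:
                    raise RegressionError(
                        f"more than 10% of bootstrap resamples were degenerate "
                        f"({n_redrawn} redraws)"
                    )
                continue
        boots[i] = coef[-1]
        i += 1

    alpha = (100.0 - ci_level) / 2.0
    ci_lo, ci_hi = np.percentile(boots, [alpha, 100.0 - alpha])
    # smallest two-sided level at which the percentile CI excludes zero
    tail = min(np.mean(boots <= 0.0), np.mean(boots >= 0.0))
    boot_p = float(min(1.0, max(2.0 * tail, 1.0 / reps)))
    return RegressionComparison(
        outcome=outcome,
        added=added,
        n=n,
        base_f=base_fit.f_statistic,
        base_df=base_fit.df,
        base_p=base_fit.p_value,
        r2_base=base_fit.r_squared,
        b=b_hat,
        ci_lower=float(ci_lo),
        ci_upper=float(ci_hi),
        boot_p=boot_p,
        significant=bool(ci_lo > 0 or ci_hi < 0),
        f_change=fch,
        f_change_df=fch_df,
        f_change_p=fch_p,
        r2_full=full_fit.r_squared,
        n_redrawn=n_redrawn,
        seed=seed,
        reps=reps,
    )
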