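"""Score orientation, descriptives, Spearman/BH, Cook's, OLS, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from tractlesion import (
    CohortConfig,
    CohortTable,
    ValidationError,
    add_bh_flags,
    benjamini_hochberg,
    bootstrap_regression,
    cook_screen,
    correlation_screen,
    f_change,
    ols_fit,
    orient_scores,
    simulate_cohort,
    spearman,
    summarize_cohort,
)
from tractlesion.errors import RegressionError
from tractlesion.stats import _half_median_quartiles


def brute_force_bh(p, q):
    """Independent oracle: maximise k over all candidates explicitly."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            best_k = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:best_k]] = True
    return flags


class TestOrientScores:
    def _cohort(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "affected_hemisphere": ["right", "left"],
                "stroop_interference": [1.2, -0.4],
                "continuous_performance": [0.3, 0.0],
                "shifting_attention": [0.5, -1.0],
            }
        )
        return CohortTable(frame=frame)

    def test_reversed_tests_flipped_others_unchanged(self):
        oc = orient_scores(self._cohort())
        assert oc.frame["stroop_interference"].tolist() == [-1.2, 0.4]
        assert oc.frame["continuous_performance"].tolist() == [-0.3, 0.0]
        assert oc.frame["shifting_attention"].tolist() == [0.5, -1.0]

    def test_double_orientation_rejected(self):
        oc = orient_scores(self._cohort())
        with pytest.raises(ValidationError):
            orient_scores(oc)


class TestDescriptives:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4, 5], (3.0, 1.5, 4.5)),
            ([7], (7.0, 7.0, 7.0)),
            ([1, 2, 3, 4], (2.5, 1.5, 3.5)),
        ],
    )
    def test_half_median_quartiles(self, values, expected):
        assert _half_median_quartiles(np.array(values)) == pytest.approx(expected)

    def test_summary_per_stratum(self):
        frame = pd.DataFrame(
            {
                "subject_id": list("abcdefg"),
                "affected_hemisphere": ["right"] * 5 + ["left"] * 2,
                "min_mean_mm": [1, 2, 3, 4, 5, 8, 10],
                "mean_fa": [0.4, 0.4, 0.4, 0.4, 0.4, 0.3, 0.5],
                "mean_md": [8e-4] * 7,
            }
        )
        summary = summarize_cohort(CohortTable(frame=frame))
        right = summary[summary.hemisphere == "right"].iloc[0]
        assert (right.min_mean_median, right.min_mean_q1, right.min_mean_q3) == (
            3.0,
            1.5,
            4.5,
        )
        assert right.mean_fa_mean == pytest.approx(0.4)
        assert right.mean_fa_sd == pytest.approx(0.0)
        assert right.mean_md_mean_e3 == pytest.approx(0.8)


class TestSpearman:
    def test_hand_example(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2)=4 -> 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)
        assert res.n == 5

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)

    def test_perfectly_monotone(self, rng):
        x = rng.normal(size=20)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_ties_match_midrank_pearson_oracle(self, rng):
        """Independent route: rank with scipy.rankdata, then plain Pearson."""
        import scipy.stats

        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(0, 5, 40).astype(float) + 0.5 * x
        expected = np.corrcoef(
            scipy.stats.rankdata(x), scipy.stats.rankdata(y)
        )[0, 1]
        assert spearman(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = [1, 2, 3, np.nan, 5]
        y = [2, 1, 4, 3, np.nan]
        assert spearman(x, y).n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestCorrelationScreen:
    def test_planted_effect_has_largest_rho_in_family(self):
        cfg = CohortConfig(
            slope_per_test={"shifting_attention": 0.15},
            md_slope_per_test={},
            noise_sd=0.5,
            seed=11,
        )
        cohort, _ = simulate_cohort(cfg)
        screen = correlation_screen(orient_scores(cohort))
        fam = screen[(screen.measure == "min_mean_mm") & (screen.hemisphere == "right")]
        assert fam.loc[fam.rho.idxmax(), "test"] == "shifting_attention"

    def test_requires_oriented_scores(self):
        cohort, _ = simulate_cohort(CohortConfig(seed=1))
        with pytest.raises(ValidationError):
            correlation_screen(cohort)

    def test_letter_fluency_pairwise_n_smaller(self):
        cohort, _ = simulate_cohort(CohortConfig(seed=2))
        screen = correlation_screen(orient_scores(cohort))
        sub = screen[(screen.measure == "min_mean_mm") & (screen.hemisphere == "right")]
        n_lf = sub[sub.test == "letter_fluency"].n.iloc[0]
        n_other = sub[sub.test == "finger_tapping"].n.iloc[0]
        assert n_lf < n_other == 32

    def test_constant_measure_flagged_not_computed(self):
        cohort, _ = simulate_cohort(CohortConfig(seed=3))
        cohort.frame["mean_fa"] = 0.4
        screen = correlation_screen(orient_scores(cohort))
        fa_rows = screen[screen.measure == "mean_fa"]
        assert not fa_rows.computed.any()


class TestBenjaminiHochberg:
    def test_six_pvalue_example(self):
        # six per-test p-values of one screen column at q=0.1: the flagged
        # set is exactly the three smallest
        p = [0.009, 0.315, 0.730, 0.049, 0.371, 0.025]
        out = benjamini_hochberg(p, q=0.1)
        np.testing.assert_array_equal(
            out.significant_flags, [True, False, False, True, False, True]
        )

    def test_all_ones_no_flags(self):
        assert benjamini_hochberg([1.0] * 5, q=0.1).n_significant == 0

    def test_single_p_reduces_to_threshold(self):
        assert benjamini_hochberg([0.04], q=0.05).n_significant == 1
        assert benjamini_hochberg([0.06], q=0.05).n_significant == 0

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            m = rng.integers(1, 12)
            p = rng.uniform(1e-6, 1.0, m)
            q = rng.uniform(0.01, 0.3)
            got = benjamini_hochberg(p, q=q).significant_flags
            np.testing.assert_array_equal(got, brute_force_bh(p, q))

    def test_flags_are_prefix_of_sorted_order(self, rng):
        p = rng.uniform(0, 1, 10)
        flags = benjamini_hochberg(p, q=0.2).significant_flags
        order = np.argsort(p)
        sorted_flags = flags[order]
        assert not np.any(np.diff(sorted_flags.astype(int)) > 0)

    def test_monotone_in_q(self, rng):
        p = rng.uniform(0, 1, 8)
        low = benjamini_hochberg(p, q=0.05).significant_flags
        high = benjamini_hochberg(p, q=0.2).significant_flags
        assert np.all(high[low])  # raising q never un-flags

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([], q=0.1)
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.0, 0.5], q=0.1)

    def test_family_grouping_configurable(self):
        cohort, _ = simulate_cohort(CohortConfig(seed=4))
        screen = correlation_screen(orient_scores(cohort))
        default = add_bh_flags(screen, q=0.1)
        pooled = add_bh_flags(screen, q=0.1, family_cols=("measure",))
        assert default.bh_q.eq(0.1).all() and pooled.bh_q.eq(0.1).all()
        assert len(default) == len(pooled)


class TestCookScreen:
    def test_displaced_point_has_max_distance(self):
        x = np.arange(10, dtype=float)
        y = 2.0 * x
        y[7] += 15.0
        d, flags = cook_screen(x, y)
        assert d.argmax() == 7
        assert flags[7]

    def test_duplicate_rows_have_equal_distances(self):
        x = np.tile([1.0, 2.0, 3.0], 4)
        y = np.tile([1.0, 4.0, 2.0], 4)
        d, _ = cook_screen(x, y)
        np.testing.assert_allclose(
            d.reshape(4, 3), np.tile(d[:3], (4, 1)), atol=1e-12
        )

    def test_matches_leave_one_out_oracle(self, rng):
        """D_i = sum_j (yhat_j - yhat_j^(i))^2 / (p * MSE), refitting
        without observation i explicitly."""
        n = 15
        X = rng.normal(size=(n, 2))
        y = X @ [1.0, -2.0] + rng.normal(0, 1, n)
        design = np.column_stack([np.ones(n), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        yhat = design @ beta
        p = design.shape[1]
        mse = np.sum((y - yhat) ** 2) / (n - p)
        expected = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            beta_i = np.linalg.lstsq(design[keep], y[keep], rcond=None)[0]
            expected[i] = np.sum((yhat - design @ beta_i) ** 2) / (p * mse)
        d, _ = cook_screen(X, y)
        np.testing.assert_allclose(d, expected, atol=1e-9)

    def test_singular_design_rejected(self):
        X = np.column_stack([np.arange(8.0), np.arange(8.0)])
        with pytest.raises(RegressionError):
            cook_screen(X, np.arange(8.0))


class TestOLSAndFChange:
    def test_exact_linear_fit(self):
        x = np.arange(10, dtype=float)
        fit = ols_fit(x, 2.0 * x)
        assert fit.coefficients[1] == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        n = 25
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        fit = ols_fit(X, y)
        design = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-9)
        sse = np.sum((y - design @ beta) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert fit.r_squared == pytest.approx(1 - sse / sst, abs=1e-9)

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(RegressionError):
            ols_fit(X, np.arange(10.0))

    def test_f_change_zero_when_no_gain(self):
        f, _, p = f_change(0.3, 0.3, 20, 2, 3)
        assert f == 0.0 and p == pytest.approx(1.0)

    def test_f_change_hand_example(self):
        f, df, _ = f_change(0.0, 0.5, 12, 0, 1)
        assert f == pytest.approx(10.0)
        assert df == (1, 10)

    def test_f_change_matches_sse_oracle(self, rng):
        """F from the R^2 form equals the nested-model SSE form."""
        n = 30
        X = rng.normal(size=(n, 3))
        y = X @ [0.5, 0.0, -1.0] + rng.normal(0, 1, n)
        base, full = ols_fit(X[:, :2], y), ols_fit(X, y)
        f, (df1, df2), _ = f_change(base.r_squared, full.r_squared, n, 2, 3)
        d_base = np.column_stack([np.ones(n), X[:, :2]])
        d_full = np.column_stack([np.ones(n), X])
        sse_b = np.sum((y - d_base @ np.linalg.lstsq(d_base, y, rcond=None)[0]) ** 2)
        sse_f = np.sum((y - d_full @ np.linalg.lstsq(d_full, y, rcond=None)[0]) ** 2)
        expected = ((sse_b - sse_f) / df1) / (sse_f / df2)
        assert f == pytest.approx(expected, abs=1e-9)

    def test_f_change_invalid_preconditions(self):
        with pytest.raises(ValidationError):
            f_change(0.2, 0.5, 20, 3, 3)
        with pytest.raises(ValidationError):
            f_change(0.5, 0.2, 20, 2, 3)


class TestBootstrapRegression:
    def _noise_free_cohort(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "affected_hemisphere": ["right"] * n,
                "tumor_grade": rng.choice([2, 3, 4], n),
                "tumor_volume_cm3": rng.uniform(5, 80, n),
                "handedness": rng.choice(["right", "left"], n, p=[0.7, 0.3]),
                "min_mean_mm": rng.uniform(1, 25, n),
            }
        )
        frame["shifting_attention"] = (
            0.5 * frame.min_mean_mm
            - 0.1 * frame.tumor_grade
            + 0.01 * frame.tumor_volume_cm3
            + 0.2 * (frame.handedness == "left")
        )
        return CohortTable(frame=frame, scores_oriented=True)

    def test_zero_noise_ci_collapses_on_true_slope(self):
        res = bootstrap_regression(
            self._noise_free_cohort(), "shifting_attention", reps=200, seed=5
        )
        assert res.b == pytest.approx(0.5, abs=1e-9)
        assert res.ci_upper - res.ci_lower < 1e-9
        assert res.significant

    def test_duplicated_predictor_rejected(self):
        cohort = self._noise_free_cohort()
        cohort.frame["min_mean_mm"] = cohort.frame["tumor_volume_cm3"]
        with pytest.raises(RegressionError):
            bootstrap_regression(cohort, "shifting_attention", reps=100, seed=0)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_regression(
                self._noise_free_cohort(), "shifting_attention", reps=50, seed=0
            )

    def test_seeded_reproducibility(self):
        cohort, _ = simulate_cohort(CohortConfig(seed=6))
        oc = orient_scores(cohort)
        a = bootstrap_regression(oc, "shifting_attention", reps=200, seed=9,
                                 hemisphere="right")
        b = bootstrap_regression(oc, "shifting_attention", reps=200, seed=9,
                                 hemisphere="right")
        assert (a.ci_lower, a.ci_upper, a.b) == (b.ci_lower, b.ci_upper, b.b)

    def test_ci_width_shrinks_with_sample_size(self):
        """Percentile CI width scales ~ 1/sqrt(n) (tolerance factor 1.5)."""
        widths = {}
        for n in (32, 128, 512):
            cfg = CohortConfig(
                n_right=n, n_left=8,
                slope_per_test={"shifting_attention": 0.061},
                md_slope_per_test={}, seed=100 + n,
            )
            cohort, _ = simulate_cohort(cfg)
            res = bootstrap_regression(
                orient_scores(cohort), "shifting_attention",
                reps=400, seed=n, hemisphere="right",
            )
            widths[n] = res.ci_upper - res.ci_lower
        for n_small, n_big in [(32, 128), (128, 512)]:
            expected_ratio = np.sqrt(n_big / n_small)
            observed_ratio = widths[n_small] / widths[n_big]
            assert expected_ratio / 1.5 < observed_ratio < expected_ratio * 1.5

    def test_f_change_and_r2_consistency(self):
        cohort, _ = simulate_cohort(CohortConfig(seed=8))
        res = bootstrap_regression(
            orient_scores(cohort), "shifting_attention", reps=200, seed=2,
            hemisphere="right",
        )
        assert res.r2_full >= res.r2_base - 1e-12
        assert res.f_change >= 0.0
        assert res.f_change_df == (1, res.n - 4 - 1)


class TestRightLeftDissociation:
    def test_planted_right_effect_dissociates_hemispheres(self):
        """With distance/MD effects planted only in right-hemisphere
        subjects, right-column BH findings appear far above the
        false-positive level while left columns stay at the nominal FDR
        rate (the dissociation is a power property, not a biological one)."""
        runs = 40
        right_hits = 0
        left_family_flags = 0
        left_families = 0
        for rep in range(runs):
            cohort, _ = simulate_cohort(CohortConfig(seed=7_000 + rep))
            screen = add_bh_flags(correlation_screen(orient_scores(cohort)), q=0.1)
            right = screen[
                (screen.hemisphere == "right")
                & screen.measure.isin(["min_mean_mm", "mean_md"])
            ]
            right_hits += int(right.bh_flag.any())
            left = screen[screen.hemisphere == "left"]
            grouped = left.groupby("measure")["bh_flag"].any()
            left_family_flags += int(grouped.sum())
            left_families += len(grouped)
        left_rate = left_family_flags / left_families
        mc_sigma = np.sqrt(0.1 * 0.9 / left_families)
        assert right_hits / runs >= 0.5
        assert left_rate <= 0.1 + 3 * mc_sigma
        assert right_hits / runs > left_rate + 0.2
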