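"""Normative statistics: OLS, laterality, growth models, z-scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mamvol.normative_models import (
    ModelError,
    analyze_laterality,
    fit_growth_quadratic,
    fit_neonatal_model,
    fit_ols,
    normative_zscore,
    peak_age,
    total_volume,
)
from mamvol.phantom_forge import (
    CORRECTED_GROWTH_COEFFS,
    GROWTH_COEFFS,
    LATERALITY_INTERCEPT,
    LATERALITY_SLOPE,
    NEONATAL_AGE_SLOPE,
    NEONATAL_SEX_OFFSET,
    child_cohort_spec,
    corrected_child_cohort_spec,
    neonatal_cohort_spec,
    simulate_cohort,
)


def _normal_equations(X, y):
    # independent oracle: explicit normal-equations solve
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitOls:
    def test_noiseless_recovery(self):
        r = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), r.random(30), r.random(30)])
        beta = np.array([2.0, -1.5, 0.25])
        fit = fit_ols(X, X @ beta, names=["c", "a", "b"])
        np.testing.assert_allclose(list(fit.terms.values()), beta, rtol=1e-8)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_gives_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        fit = fit_ols(np.ones((4, 1)), y, names=["intercept"])
        assert fit.terms["intercept"] == pytest.approx(y.mean())

    def test_agrees_with_normal_equations_oracle(self):
        r = np.random.default_rng(42)
        X = np.column_stack([np.ones(20), r.standard_normal((20, 2))])
        y = r.standard_normal(20)
        fit = fit_ols(X, y)
        np.testing.assert_allclose(
            list(fit.terms.values()), _normal_equations(X, y), rtol=1e-8
        )

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ModelError):
            fit_ols(X, np.arange(10.0))

    def test_more_terms_than_rows_rejected(self):
        with pytest.raises(ModelError):
            fit_ols(np.eye(3), np.arange(3.0))


class TestLaterality:
    def _cohort(self, left, right, age=None, sex=None):
        n = len(left)
        return pd.DataFrame(
            {
                "age": age if age is not None else np.linspace(6, 24, n),
                "sex": sex if sex is not None else ["male", "female"] * (n // 2),
                "left_mb_mm3": left,
                "right_mb_mm3": right,
            }
        )

    def test_equal_sides_give_identity_map(self):
        v = np.linspace(30, 60, 20)
        fit = analyze_laterality(self._cohort(v, v))
        assert fit.paired_mean_diff_mm3 == pytest.approx(0.0)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_printed_map_recovered_exactly(self):
        right = np.linspace(20, 60, 50)
        left = LATERALITY_INTERCEPT + LATERALITY_SLOPE * right
        fit = analyze_laterality(self._cohort(left, right))
        assert fit.slope == pytest.approx(LATERALITY_SLOPE, rel=1e-6)
        assert fit.intercept == pytest.approx(LATERALITY_INTERCEPT, rel=1e-6)

    def test_small_constant_offset_detected(self):
        # paired-t power at +1 mm^3 offset, sd 0.5, n=200
        r = np.random.default_rng(7)
        right = r.uniform(30, 60, 200)
        left = right + 1.0 + r.normal(0, 0.5, 200)
        fit = analyze_laterality(self._cohort(left, right))
        assert fit.paired_p < 1e-3
        assert fit.paired_mean_diff_mm3 > 0

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ModelError):
            analyze_laterality(self._cohort(np.ones(2), np.ones(2), age=[1, 2], sex=["male", "female"]))


class TestNeonatalModel:
    def test_printed_slope_and_sex_offset_recovered(self):
        df = simulate_cohort(neonatal_cohort_spec(n=120, residual_sd=0.0, seed=3))
        fit = fit_neonatal_model(df)
        assert fit.terms["age"] == pytest.approx(NEONATAL_AGE_SLOPE, rel=1e-6)
        assert fit.terms["sex_male"] == pytest.approx(NEONATAL_SEX_OFFSET, rel=1e-6)

    def test_optional_covariates_join_design(self):
        df = simulate_cohort(neonatal_cohort_spec(n=120, seed=4))
        fit = fit_neonatal_model(df, include_ga_birth=True, include_prematurity=True)
        assert set(fit.terms) == {"intercept", "age", "sex_male", "ga_birth", "premature"}

    def test_missing_covariate_named_in_error(self):
        df = simulate_cohort(neonatal_cohort_spec(n=50, seed=5)).drop(columns=["ga_birth"])
        with pytest.raises(ModelError, match="ga_birth"):
            fit_neonatal_model(df, include_ga_birth=True)

    def test_single_sex_cohort_rank_error(self):
        df = simulate_cohort(neonatal_cohort_spec(n=50, seed=6))
        df["sex"] = "male"
        with pytest.raises(ModelError):
            fit_neonatal_model(df)


class TestGrowthQuadratic:
    def test_printed_equation_recovered(self):
        df = simulate_cohort(child_cohort_spec(n=100, residual_sd=0.0, seed=7))
        fit = fit_growth_quadratic(df)
        for name, expect in zip(["intercept", "age", "age2"], GROWTH_COEFFS):
            assert fit.terms[name] == pytest.approx(expect, rel=1e-6)

    def test_corrected_equation_recovered(self):
        df = simulate_cohort(corrected_child_cohort_spec(n=100, residual_sd=0.0, seed=8))
        fit = fit_growth_quadratic(df, corrected=True)
        for name, expect in zip(["intercept", "age", "age2"], CORRECTED_GROWTH_COEFFS):
            assert fit.terms[name] == pytest.approx(expect, rel=1e-8)

    def test_pure_line_has_zero_curvature(self):
        age = np.linspace(6, 24, 40)
        df = pd.DataFrame(
            {
                "age": age,
                "sex": ["male"] * 40,
                "left_mb_mm3": 10 + 2 * age,
                "right_mb_mm3": 10 + 2 * age,
            }
        )
        fit = fit_growth_quadratic(df)
        assert abs(fit.terms["age2"]) < 1e-8

    def test_corrected_requires_icv(self):
        df = simulate_cohort(child_cohort_spec(n=30, seed=9)).drop(columns=["icv_cm3"])
        with pytest.raises(ModelError, match="icv_cm3"):
            fit_growth_quadratic(df, corrected=True)

    def test_total_is_exact_sum(self):
        df = simulate_cohort(child_cohort_spec(n=30, seed=10))
        np.testing.assert_array_equal(
            total_volume(df), (df.left_mb_mm3 + df.right_mb_mm3).to_numpy()
        )


class TestPeakAge:
    def test_vertex_formula(self):
        fit = fit_ols(
            np.column_stack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2]),
            0 + 4 * np.arange(5.0) - 1 * np.arange(5.0) ** 2,
            names=["intercept", "age", "age2"],
        )
        assert peak_age(fit) == pytest.approx(2.0)

    def test_printed_raw_curve_peaks_past_seventeen(self):
        df = simulate_cohort(child_cohort_spec(n=60, residual_sd=0.0, seed=11))
        assert peak_age(fit_growth_quadratic(df)) == pytest.approx(6.53 / (2 * 0.19), rel=1e-6)

    def test_printed_corrected_curve_peak(self):
        df = simulate_cohort(corrected_child_cohort_spec(n=60, residual_sd=0.0, seed=12))
        fit = fit_growth_quadratic(df, corrected=True)
        assert peak_age(fit) == pytest.approx(2.52e-3 / (2 * 7.349e-5), rel=1e-6)

    def test_non_concave_rejected(self):
        fit = fit_ols(
            np.column_stack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2]),
            np.arange(5.0) ** 2,
            names=["intercept", "age", "age2"],
        )
        with pytest.raises(ModelError):
            peak_age(fit)


class TestZScore:
    @pytest.fixture(scope="class")
    def growth_fit(self):
        df = simulate_cohort(child_cohort_spec(n=1000, residual_sd=12.0, seed=13))
        return fit_growth_quadratic(df), df

    def test_observed_equals_predicted(self, growth_fit):
        fit, _ = growth_fit
        z, pct = normative_zscore(fit, 12.0, fit.predict(12.0))
        assert z == pytest.approx(0.0, abs=1e-12)
        assert pct == pytest.approx(50.0)

    def test_one_sd_above(self, growth_fit):
        fit, _ = growth_fit
        z, _ = normative_zscore(fit, 12.0, fit.predict(12.0) + fit.residual_sd)
        assert z == pytest.approx(1.0)

    def test_percentile_symmetry(self, growth_fit):
        fit, _ = growth_fit
        zp, pp = normative_zscore(fit, 10.0, fit.predict(10.0) + 7.0)
        zm, pm = normative_zscore(fit, 10.0, fit.predict(10.0) - 7.0)
        assert zp == pytest.approx(-zm)
        assert pp == pytest.approx(100.0 - pm)

    def test_generating_cohort_zscores_standard_normal(self, growth_fit):
        fit, df = growth_fit
        zs = [
            normative_zscore(fit, a, v)[0]
            for a, v in zip(df.age, df.left_mb_mm3 + df.right_mb_mm3)
        ]
        assert stats.kstest(zs, "norm").pvalue > 0.01

    def test_zero_residual_sd_rejected(self):
        from dataclasses import replace

        df = simulate_cohort(child_cohort_spec(n=30, residual_sd=0.0, seed=14))
        fit = replace(fit_growth_quadratic(df), residual_sd=0.0)
        with pytest.raises(ModelError):
            normative_zscore(fit, 12.0, 100.0)
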