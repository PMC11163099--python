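"""QSPR regression: estimates, inference statistics, prediction tables."""

import math

import numpy as np
import pytest
from scipy import integrate, special

from topoqspr import (
    DegenerateDataError,
    TopoIndexQSPR,
    correlation_table,
    f_upper_tail,
    fit_all_models,
    fit_simple_ols,
    prediction_table,
    regression_stats,
)


def fit_via_normal_equations(x, y):
    """Independent oracle: solve the 2x2 normal equations directly."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    return float(beta[0]), float(beta[1])


class TestFitSimpleOLS:
    def test_forgotten_index_melting_point_coefficients(self, sulfonamides):
        res = TopoIndexQSPR.from_compounds(sulfonamides, "F", "melting_point").fit()
        assert res.A == pytest.approx(369.886126342673, rel=1e-9)
        assert res.B == pytest.approx(-0.425261023060167, rel=1e-9)

    def test_perfect_line(self):
        x = [1.0, 2.0, 4.0, 7.0]
        y = [2 * v + 1 for v in x]
        a, b = fit_simple_ols(x, y)
        assert (a, b) == (pytest.approx(1.0), pytest.approx(2.0))
        st = regression_stats(x, y, a, b)
        assert st["se_estimate"] == pytest.approx(0.0, abs=1e-12)
        assert st["r_abs"] == pytest.approx(1.0)
        assert math.isinf(st["f_stat"]) and st["p_value"] == 0.0
        assert st["boundary"]

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=8)
        y = 3.0 - 2.5 * x + rng.normal(size=8)
        a, b = fit_simple_ols(x, y)
        a0, b0 = fit_via_normal_equations(x, y)
        assert a == pytest.approx(a0, abs=1e-9)
        assert b == pytest.approx(b0, abs=1e-9)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, size=12)
        y = 5 + 0.7 * x + rng.normal(size=12)
        a, b = fit_simple_ols(x, y)
        st = regression_stats(x, y, a, b)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert a == pytest.approx(ols.params[0], rel=1e-9)
        assert b == pytest.approx(ols.params[1], rel=1e-9)
        assert st["f_stat"] == pytest.approx(ols.fvalue, rel=1e-9)
        assert st["p_value"] == pytest.approx(ols.f_pvalue, rel=1e-9)
        assert st["r2"] == pytest.approx(ols.rsquared, rel=1e-9)
        assert st["se_estimate"] == pytest.approx(np.sqrt(ols.scale), rel=1e-9)

    def test_line_passes_through_centroid(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        a, b = fit_simple_ols(x, y)
        assert a + b * x.mean() == pytest.approx(y.mean(), rel=1e-9)

    def test_residuals_sum_to_zero(self, sulfonamides):
        res = TopoIndexQSPR.from_compounds(sulfonamides, "M1", "melting_point").fit()
        scale = float(np.abs(res.y).max())
        assert abs(res.residuals.sum()) < 1e-9 * scale

    def test_insufficient_data_rejected(self):
        with pytest.raises(DegenerateDataError, match="at least 3"):
            fit_simple_ols([1.0, 2.0], [3.0, 4.0])

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDataError, match="zero variance"):
            fit_simple_ols([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_constant_response_rejected(self):
        x = [1.0, 2.0, 3.0]
        y = [5.0, 5.0, 5.0]
        with pytest.raises(DegenerateDataError, match="zero variance"):
            regression_stats(x, y, *fit_simple_ols(x, y))


class TestInferenceStats:
    def test_melting_point_on_forgotten_index_row(self, sulfonamides):
        res = TopoIndexQSPR.from_compounds(sulfonamides, "F", "melting_point").fit()
        assert res.r_abs == pytest.approx(0.9114, abs=0.001)
        assert res.r2 == pytest.approx(0.8307, abs=0.001)
        assert res.f_stat == pytest.approx(14.721, abs=0.001)
        assert res.p_value == pytest.approx(0.0312, abs=0.0005)
        assert res.significant and res.indicator == "Significant"

    def test_hyper_zagreb_melting_point_is_significant(self, sulfonamides):
        res = TopoIndexQSPR.from_compounds(sulfonamides, "HM", "melting_point").fit()
        assert res.p_value == pytest.approx(0.0471, abs=0.0005)
        assert res.significant

    def test_f_stat_consistency_identity(self, sulfonamides):
        for (prop, idx), res in fit_all_models(sulfonamides).items():
            assert res.r2 == pytest.approx(res.r_abs**2, abs=1e-12)
            if res.r2 < 1:
                assert res.f_stat == pytest.approx(
                    res.r2 * (res.n - 2) / (1 - res.r2), abs=1e-9
                )
            assert res.significant == (res.p_value < 0.05)

    def test_slope_sign_kept_but_reported_r_positive(self, sulfonamides):
        res = TopoIndexQSPR.from_compounds(sulfonamides, "M1", "melting_point").fit()
        assert res.B < 0
        assert res.r_signed < 0
        assert res.summary().iloc[0]["r"] == pytest.approx(0.8447, abs=0.001)


class TestFUpperTail:
    def quad_oracle(self, f, df1, df2):
        """Numeric integration of the F(df1, df2) density above f."""

        def density(t):
            c = (df1 / df2) ** (df1 / 2) / special.beta(df1 / 2, df2 / 2)
            return c * t ** (df1 / 2 - 1) * (1 + df1 * t / df2) ** (-(df1 + df2) / 2)

        val, _ = integrate.quad(density, f, np.inf, limit=200)
        return val

    def test_zero_statistic(self):
        assert f_upper_tail(0.0, 1, 3) == 1.0

    def test_reported_p_value(self):
        assert f_upper_tail(14.7216, 1, 3) == pytest.approx(0.0312, abs=0.0005)

    @pytest.mark.parametrize("df2", [3, 5, 10])
    def test_agrees_with_quadrature_oracle(self, df2):
        for f in [0.1, 0.5, 1.0, 5.0, 14.72, 30.0, 50.0]:
            assert f_upper_tail(f, 1, df2) == pytest.approx(
                self.quad_oracle(f, 1, df2), abs=1e-6
            )

    def test_strictly_decreasing(self):
        grid = np.linspace(0, 50, 60)
        vals = [f_upper_tail(f, 1, 3) for f in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            f_upper_tail(1.0, 0, 3)
        with pytest.raises(ValueError):
            f_upper_tail(-1.0, 1, 3)


class TestCorrelationTable:
    def test_study_melting_point_correlations(self, sulfonamides):
        table = correlation_table(sulfonamides)
        assert table.loc["M1", "melting_point"] == pytest.approx(0.844704869, abs=1e-6)
        assert table.loc["HM", "melting_point"] == pytest.approx(0.883144781, abs=1e-6)
        assert table.loc["F", "melting_point"] == pytest.approx(0.911434835, abs=1e-6)
        assert ((table >= 0) & (table <= 1)).all().all()

    def test_formula_weight_correlations_weak(self, sulfonamides):
        table = correlation_table(sulfonamides)
        assert table.loc["F", "formula_weight"] == pytest.approx(0.003982157, abs=1e-6)
        assert (table["formula_weight"] < 0.25).all()

    def test_degenerate_response_annotated_not_fatal(self, sulfonamides):
        flat = [
            type(rec)(
                name=rec.name,
                partition=rec.partition,
                melting_point=rec.melting_point,
                formula_weight=100.0,
            )
            for rec in sulfonamides
        ]
        table = correlation_table(flat)
        assert table["formula_weight"].isna().all()
        assert table["melting_point"].notna().all()

    def test_too_few_compounds_rejected(self, sulfonamides):
        with pytest.raises(DegenerateDataError):
            correlation_table(sulfonamides[:2])


class TestPrediction:
    def test_melting_point_from_forgotten_index(self, sulfonamides):
        res = TopoIndexQSPR.from_compounds(sulfonamides, "F", "melting_point").fit()
        assert res.predict(420.0) == pytest.approx(191.28, abs=0.01)

    def test_formula_weight_from_first_zagreb(self, sulfonamides):
        res = TopoIndexQSPR.from_compounds(sulfonamides, "M1", "formula_weight").fit()
        assert res.predict(136.0) == pytest.approx(353.18, abs=0.01)

    def test_prediction_at_mean_is_mean_response(self, sulfonamides):
        res = TopoIndexQSPR.from_compounds(sulfonamides, "S", "melting_point").fit()
        assert res.predict(res.x.mean()) == pytest.approx(res.y.mean(), rel=1e-12)

    def test_prediction_table_shape_and_subset(self, sulfonamides):
        fits = fit_all_models(sulfonamides)
        table = prediction_table(fits, sulfonamides, "melting_point", indices=["F"])
        assert list(table.columns) == ["actual", "F"]
        assert len(table) == 5
        assert table["actual"].tolist() == [191, 140, 133, 210, 148]
        assert table["F"].iloc[3] == pytest.approx(191.28, abs=0.01)
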