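"""OLS fitting, QSAR metrics, correlation analysis, and the model registry."""

import numpy as np
import pandas as pd
import pytest

from fdtox import (
    GeneratorConfig,
    build_registry,
    correlation_matrix,
    evaluate,
    fit_ols,
    generate_dataset,
    implied_response_correlation,
)
from fdtox.errors import (
    DimensionError,
    MetricError,
    RegistryError,
    SingularityError,
)
from fdtox.regression import MODEL_NAMES

RNG = np.random.default_rng(99)


class TestFitOls:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 10, 30)
        model = fit_ols(x[:, None], 2 * x + 1, predictor_names=["x"])
        assert model.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert model.r2_train == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_has_negligible_r2(self):
        X = RNG.normal(size=(1000, 2))
        y = RNG.normal(size=1000)
        assert fit_ols(X, y).r2_train <= 0.05

    def test_constant_response_rejected(self):
        with pytest.raises(MetricError):
            fit_ols(RNG.normal(size=(20, 2)), np.ones(20))

    def test_rank_deficiency_names_collinear_columns(self):
        X = RNG.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])     # exact duplicate direction
        y = RNG.normal(size=30)
        with pytest.raises(SingularityError, match="x2"):
            fit_ols(X, y, predictor_names=["x0", "x1", "x2"])

    def test_too_few_observations_rejected(self):
        with pytest.raises(SingularityError):
            fit_ols(RNG.normal(size=(4, 3)), RNG.normal(size=4))

    @pytest.mark.parametrize("n", [8, 12, 20])
    def test_coefficients_match_normal_equations_oracle(self, n):
        X = RNG.normal(size=(n, 3))
        y = RNG.normal(size=n)
        model = fit_ols(X, y)
        design = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(model.intercept, beta[0], atol=1e-8)
        assert np.allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_irrelevant_predictor_never_decreases_training_r2(self):
        X = RNG.normal(size=(50, 2))
        y = X @ [1.0, -2.0] + RNG.normal(0, 0.5, 50)
        base = fit_ols(X, y).r2_train
        extended = fit_ols(np.column_stack([X, RNG.normal(size=50)]), y).r2_train
        assert extended >= base - 1e-12


class TestEvaluate:
    def test_perfect_predictions_give_unit_q2(self):
        y = RNG.normal(size=40)
        m = evaluate(y, y)
        assert m["q2"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_fools_q2_but_not_rmse(self):
        y = RNG.normal(size=40)
        m = evaluate(y, y + 3.0)
        assert m["q2"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(3.0)
        assert m["q2_press"] < 1.0          # the PRESS variant sees the shift

    def test_anti_correlated_predictions_warn(self):
        y = np.linspace(0, 1, 30)
        with pytest.warns(UserWarning, match="anti-correlated"):
            m = evaluate(y, -y)
        assert m["q2"] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            evaluate(np.zeros(5), np.zeros(6))


class TestCorrelationMatrix:
    def test_self_and_negated_correlations(self):
        x = RNG.normal(size=50)
        df = pd.DataFrame({"x": x, "neg": -x, "noise": RNG.normal(size=50)})
        C = correlation_matrix(df)
        assert C.loc["x", "x"] == pytest.approx(1.0)
        assert C.loc["x", "neg"] == pytest.approx(-1.0)
        assert np.allclose(C, C.T)
        assert (C.abs() <= 1 + 1e-12).all().all()

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"a": RNG.normal(size=10), "flat": np.ones(10)})
        with pytest.raises(MetricError, match="flat"):
            correlation_matrix(df)

    def test_single_column_rejected(self):
        with pytest.raises(MetricError):
            correlation_matrix(pd.DataFrame({"a": RNG.normal(size=10)}))

    def test_synthetic_responses_match_analytic_window(self, default_dataset):
        C = correlation_matrix(default_dataset.response_table)
        A = implied_response_correlation(GeneratorConfig())
        off = ~np.eye(len(C), dtype=bool)
        assert C.values[off].min() == pytest.approx(A.values[off].min(), abs=0.12)
        assert C.values[off].max() == pytest.approx(A.values[off].max(), abs=0.06)


SMALL_CP = {
    "ALL_CPANN": {"grid_n": 7, "n_epochs": 40},
    "cpann_1": {"grid_n": 7, "n_epochs": 40},
    "cpann_2": {"grid_n": 5, "n_epochs": 30},
}
SMALL_DCW = {"n_epochs": 8}


@pytest.fixture(scope="module")
def registry(small_dataset):
    return build_registry(small_dataset, cpann_params=SMALL_CP,
                          dcw_params=SMALL_DCW, seed=3)


class TestRegistry:
    def test_six_models_by_twelve_responses(self, registry):
        assert sorted(registry.summary["model"].unique()) == sorted(MODEL_NAMES)
        counts = registry.summary.groupby("model").size()
        assert (counts == 12).all()
        assert len(registry.summary) == 72

    def test_predictor_sets_follow_the_plan(self, registry):
        assert registry.regressions[("regression_1", "1GOS")].predictor_names == [
            "QPpolrz", "TD"]
        assert registry.regressions[("regression_2", "1GOS")].predictor_names == [
            "DCW"]
        assert len(registry.regressions[("ALL_regression", "1GOS")].predictor_names) > 2

    def test_registry_reproducible_from_config(self, small_dataset, registry):
        again = build_registry(small_dataset, cpann_params=SMALL_CP,
                               dcw_params=SMALL_DCW, seed=3)
        pd.testing.assert_frame_equal(registry.summary, again.summary)

    def test_missing_predictor_columns_listed(self, small_dataset):
        import copy

        broken = copy.copy(small_dataset)
        broken.descriptor_table = small_dataset.descriptor_table.drop(columns=["TD"])
        with pytest.raises(RegistryError, match="TD"):
            build_registry(broken, cpann_params=SMALL_CP, dcw_params=SMALL_DCW)

    def test_r2_equals_squared_observed_fitted_correlation(self, small_dataset, registry):
        model = registry.regressions[("regression_1", "AverageBScore")]
        y = small_dataset.response_table.loc[small_dataset.train_ids(), "AverageBScore"]
        df = pd.DataFrame({"obs": y.to_numpy(), "fit": model.fitted_values})
        r = correlation_matrix(df).loc["obs", "fit"]
        assert model.r2_train == pytest.approx(r ** 2, abs=1e-12)
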