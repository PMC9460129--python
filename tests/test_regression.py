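"""Model enumeration, OLS fitting, LOSO selection, frozen equations."""

import numpy as np
import pandas as pd
import pytest

from vibrotact.regression import (
    ExhaustiveTactileRegressor,
    InfeasibleModelError,
    ModelSpec,
    design_matrix,
    enumerate_specs,
    evaluate_frozen,
    fit_spec,
    loso_error,
    select_models,
)

CANDIDATES = ["D_a", "D_b", "D_c", "D_d", "D_e", "mu_prime"]


def sample_table(rng, n=8, cols=("D_a",), spread=2.0):
    data = {
        c: 10.0 * 10 ** rng.uniform(0, spread, n) for c in cols
    }
    return pd.DataFrame(data, index=[f"s{i}" for i in range(n)])


class TestEnumeration:
    def test_interaction_over_six_candidates_is_15(self):
        assert len(enumerate_specs("interaction", CANDIDATES)) == 15

    def test_linear_subsets_up_to_5_of_6_is_62(self):
        from math import comb

        specs = enumerate_specs("linear", CANDIDATES, p_max=5)
        assert len(specs) == sum(comb(6, p) for p in range(1, 6)) == 62

    def test_polynomial_one_spec_per_variable(self):
        specs = enumerate_specs("polynomial", CANDIDATES, a_max=3)
        assert len(specs) == 6
        assert all(s.degree == 3 and len(s.variables) == 1 for s in specs)

    def test_p_max_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            specs = enumerate_specs("linear", ["x", "y"], p_max=5)
        assert len(specs) == 3

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            enumerate_specs("linear", [])

    def test_spec_structural_constraints(self):
        with pytest.raises(ValueError):
            ModelSpec("interaction", ("x",))
        with pytest.raises(ValueError):
            ModelSpec("polynomial", ("x", "y"))
        with pytest.raises(ValueError):
            ModelSpec("sigmoid", ("x",))


class TestDesignMatrix:
    def test_linear_single_variable_shape(self):
        X = pd.DataFrame({"D_a": np.arange(8.0)})
        M, cols = design_matrix(ModelSpec("linear", ("D_a",)), X)
        assert M.shape == (8, 2)
        assert (M[:, 0] == 1).all()

    def test_interaction_row_contains_product(self):
        X = pd.DataFrame({"x": [2.0], "y": [3.0]})
        M, cols = design_matrix(ModelSpec("interaction", ("x", "y")), X)
        assert M[0].tolist() == [1.0, 2.0, 3.0, 6.0]

    def test_polynomial_powers(self):
        X = pd.DataFrame({"x": [2.0]})
        M, _ = design_matrix(ModelSpec("polynomial", ("x",), degree=3), X)
        assert M[0].tolist() == [1.0, 2.0, 4.0, 8.0]

    def test_logarithmic_uses_log10(self):
        X = pd.DataFrame({"x": [100.0]})
        M, cols = design_matrix(ModelSpec("logarithmic", ("x",)), X)
        assert M[0, 1] == pytest.approx(2.0)
        assert cols == ["log10(x)"]

    def test_log_of_nonpositive_is_infeasible(self):
        X = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(InfeasibleModelError):
            design_matrix(ModelSpec("logarithmic", ("x",)), X)

    def test_missing_column_raises_keyerror(self):
        with pytest.raises(KeyError):
            design_matrix(ModelSpec("linear", ("nope",)), pd.DataFrame({"x": [1.0]}))


class TestFit:
    def test_noiseless_line_recovered(self):
        X = pd.DataFrame({"x": np.arange(8.0)})
        y = 2.0 * X["x"] + 1.0
        m = fit_spec(ModelSpec("linear", ("x",)), X, y)
        assert m.r_squared == pytest.approx(1.0)
        assert m.params["const"] == pytest.approx(1.0)
        assert m.params["x"] == pytest.approx(2.0)

    def test_standardized_coefficient_equals_pearson_r(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=30)})
        y = 0.6 * X["x"] + rng.normal(scale=0.5, size=30)
        m = fit_spec(ModelSpec("linear", ("x",)), X, y)
        r = np.corrcoef(X["x"], y)[0, 1]
        assert m.std_params["x"] == pytest.approx(r, abs=1e-10)

    def test_against_normal_equation_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        y = rng.normal(size=8)
        m = fit_spec(ModelSpec("linear", ("a", "b")), X, y)
        M = np.column_stack([np.ones(8), X["a"], X["b"]])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        assert m.params.to_numpy() == pytest.approx(beta, abs=1e-10)

    def test_standardization_identity(self, rng):
        """Refitting on z-scored columns reproduces the standardized betas."""
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = pd.Series(X["a"] - 2 * X["b"] + rng.normal(scale=0.3, size=20))
        m = fit_spec(ModelSpec("linear", ("a", "b")), X, y)
        Xz = (X - X.mean()) / X.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        mz = fit_spec(ModelSpec("linear", ("a", "b")), Xz, yz)
        assert mz.params["a"] == pytest.approx(m.std_params["a"], abs=1e-8)
        assert mz.params["b"] == pytest.approx(m.std_params["b"], abs=1e-8)

    def test_more_regressors_never_lower_r2(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        y = X["a"] + rng.normal(scale=0.5, size=8)
        r2_small = fit_spec(ModelSpec("linear", ("a",)), X, y).r_squared
        r2_big = fit_spec(ModelSpec("linear", ("a", "b", "c")), X, y).r_squared
        assert r2_big >= r2_small
        assert r2_big >= fit_spec(ModelSpec("linear", ("a", "b", "c")), X, y).r_squared_adj

    def test_rank_deficiency_is_infeasible(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(InfeasibleModelError):
            fit_spec(ModelSpec("linear", ("a", "b")), X, np.arange(4.0))

    def test_underdetermined_is_infeasible(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [5.0, 3.0]})
        with pytest.raises(InfeasibleModelError):
            fit_spec(ModelSpec("linear", ("a", "b")), X, np.arange(2.0))


class TestLOSO:
    def test_noiseless_linear_gives_zero_error(self, rng):
        X = sample_table(rng)
        y = pd.Series(3.0 + 0.01 * X["D_a"], index=X.index)
        cv = loso_error(ModelSpec("linear", ("D_a",)), X, y)
        assert cv.error == pytest.approx(0.0, abs=1e-18)
        assert len(cv.fold_errors) == len(X)

    def test_order_invariance(self, rng):
        X = sample_table(rng)
        y = pd.Series(rng.normal(size=len(X)), index=X.index)
        spec = ModelSpec("linear", ("D_a",))
        e1 = loso_error(spec, X, y).error
        perm = rng.permutation(len(X))
        e2 = loso_error(spec, X.iloc[perm], y.iloc[perm]).error
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_planted_log_beats_linear_in_95_of_100(self):
        from vibrotact.simulate import planted_regression_study

        study = planted_regression_study(n_replicates=100, noise_sd=0.01, seed=11)
        assert (study["winner"] == "logarithmic").sum() >= 95
        won = study[study["winner"] == "logarithmic"]
        assert (won["beta0_rel_err"] < 0.05).all()
        assert (won["beta1_rel_err"] < 0.05).all()

    def test_too_few_samples(self, rng):
        X = sample_table(rng, n=2)
        with pytest.raises(ValueError):
            loso_error(ModelSpec("linear", ("D_a",)), X, pd.Series([1.0, 2.0], index=X.index))


class TestSelection:
    def test_planted_log_target_selects_log_cell(self, rng):
        X = sample_table(rng, cols=("D_a", "mu_prime"))
        y = pd.DataFrame(
            {"PC1": 2.0 + 1.5 * np.log10(X["D_a"]) + rng.normal(0, 0.01, len(X))}
        )
        res = select_models({"A": X, "B": X}, y, p_max=2)
        winner = res.best["PC1"]
        assert winner.spec.family == "logarithmic"
        # identical feature tables for both methods -> identical minima
        a = res.grid.loc["PC1", "A"].to_numpy(float)
        b = res.grid.loc["PC1", "B"].to_numpy(float)
        assert a == pytest.approx(b)

    def test_grid_has_all_cells(self, rng):
        X = sample_table(rng, cols=("D_a",))
        y = pd.DataFrame({"PC1": rng.normal(size=len(X))}, index=X.index)
        res = select_models({"B": X}, y, a_max=3)
        assert res.grid.shape == (1, 4)
        assert ("PC1", "B", "polynomial") in res.cell_best
        assert res.cell_best[("PC1", "B", "polynomial")].spec.degree in (1, 2, 3)

    def test_selection_deterministic(self, rng):
        X = sample_table(rng, cols=("D_a", "D_b"))
        y = pd.DataFrame({"PC1": rng.normal(size=len(X))}, index=X.index)
        r1 = select_models({"B": X}, y)
        r2 = select_models({"B": X}, y)
        assert r1.best["PC1"].spec == r2.best["PC1"].spec
        assert r1.grid.equals(r2.grid)

    def test_estimator_api_fit_predict(self, rng):
        X = sample_table(rng, cols=("D_a", "D_b"))
        y = 1.0 + 0.5 * np.log10(X["D_a"])
        reg = ExhaustiveTactileRegressor(families=("linear", "logarithmic"), p_max=2)
        reg.fit(X, y)
        assert reg.best_spec_.family == "logarithmic"
        pred = reg.predict(X)
        assert pred == pytest.approx(y.to_numpy(), abs=1e-8)

    @pytest.mark.parametrize("sigma", [0.1, 0.01, 0.001])
    def test_coefficients_converge_with_vanishing_noise(self, sigma):
        rng = np.random.default_rng(99)
        X = sample_table(rng, cols=("D_a",))
        y = pd.Series(
            2.0 + 1.5 * np.log10(X["D_a"]) + rng.normal(0, sigma, len(X)), index=X.index
        )
        reg = ExhaustiveTactileRegressor(families=("logarithmic",), p_max=1).fit(X, y)
        err = abs(float(reg.model_.params.iloc[1]) - 1.5)
        assert err < 10 * sigma


class TestFrozenEquations:
    @pytest.mark.parametrize(
        "model_id,features,expected",
        [
            ("C1PC2", {"D_SAIIFAII": 0.0}, 0.0),
            ("C2PC1", {"D_SAISAIIFAI": 1.0, "mu_prime": 1.0}, -16.88),
            (
                "C2PC2",
                {"D_SAISAIIFAII": 0.0, "D_ALL": 0.0, "D_SAIIFAII": 0.0},
                -94.98,
            ),
            ("C2PC3", {"D_SAISAIIFAII": 0.0, "D_SAIIFAII": 0.0, "D_SAISAIIFAI": 5.0}, 4911.0),
            (
                "C1PC1",
                {"D_SAISAIIFAI": 1.0, "D_SAIIFAII": 1.0, "D_FAII": 10.0, "mu_prime": 1.0},
                -4136.0 + 466.3,
            ),
        ],
    )
    def test_published_equation_values(self, model_id, features, expected):
        assert evaluate_frozen(model_id, features) == pytest.approx(expected)

    def test_missing_feature_named(self):
        with pytest.raises(KeyError, match="mu_prime"):
            evaluate_frozen("C2PC1", {"D_SAISAIIFAI": 1.0})

    def test_log_argument_must_be_positive(self):
        with pytest.raises(ValueError):
            evaluate_frozen("C2PC1", {"D_SAISAIIFAI": 0.0, "mu_prime": 1.0})

    def test_unknown_model_id(self):
        with pytest.raises(KeyError):
            evaluate_frozen("C9PC9", {})
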