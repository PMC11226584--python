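"""Elastic-net age model: solver, lambda selection, bias correction, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import braingap as bg
from braingap.model import (_enet_solve, auto_lambda_grid,
                            elastic_net_objective, kkt_violation)

from _enet_oracle import enet_coordinate_descent


def _standardized(res, model):
    Xs = (model.X - res.feature_mean) / res.feature_scale
    return Xs, model.ages - model.ages.mean()


class TestFit:
    def test_single_informative_feature(self, rng):
        n = 40
        ages = rng.uniform(55, 90, n)
        X = np.zeros((n, 6))
        X[:, 0] = ages
        cfg = bg.FitConfig(n_folds=4, n_repeats=1, selection_rule="min",
                           lambda_grid=[1e-2, 1e-4], seed=0)
        res = bg.BrainAgeModel(X, ages, cfg).fit()
        m = bg.evaluate(res.fitted_values(), ages)
        assert m.mae < 0.1

    def test_full_shrinkage_limit(self, rng):
        n, p = 40, 10
        X = rng.standard_normal((n, p))
        ages = rng.uniform(55, 90, n)
        Xs = (X - X.mean(0)) / X.std(0)
        lam_max = float(np.max(np.abs(Xs.T @ (ages - ages.mean()))) / (n * 0.5))
        cfg = bg.FitConfig(n_folds=4, n_repeats=1,
                           lambda_grid=[2 * lam_max, 1.5 * lam_max], seed=1)
        res = bg.BrainAgeModel(X, ages, cfg).fit()
        assert res.n_nonzero == 0
        np.testing.assert_allclose(res.fitted_values(), ages.mean(), atol=1e-10)

    def test_kkt_conditions_at_solution(self, rng):
        n, p = 50, 30
        X = rng.standard_normal((n, p))
        ages = 70 + X[:, 0] * 3 + rng.normal(0, 1, n)
        cfg = bg.FitConfig(n_folds=5, n_repeats=2, n_lambda=30, seed=2)
        model = bg.BrainAgeModel(X, ages, cfg)
        res = model.fit()
        Xs, yc = _standardized(res, model)
        w_std = res.weights * res.feature_scale
        assert kkt_violation(Xs, yc, w_std, res.lambda_selected, 0.5) < 1e-5

    def test_objective_not_worse_than_zero(self, rng):
        n, p = 30, 12
        X = rng.standard_normal((n, p))
        ages = 70 + rng.normal(0, 5, n)
        cfg = bg.FitConfig(n_folds=3, n_repeats=1, n_lambda=20, seed=3)
        model = bg.BrainAgeModel(X, ages, cfg)
        res = model.fit()
        Xs, yc = _standardized(res, model)
        w_std = res.weights * res.feature_scale
        obj = elastic_net_objective(Xs, yc, w_std, res.lambda_selected, 0.5)
        obj0 = elastic_net_objective(Xs, yc, np.zeros_like(w_std),
                                     res.lambda_selected, 0.5)
        assert obj <= obj0 + 1e-12

    def test_solver_matches_independent_oracle(self, rng):
        n, p = 30, 8
        X = rng.standard_normal((n, p))
        y = X @ rng.normal(0, 1, p) + rng.normal(0, 0.5, n)
        y -= y.mean()
        lam = 0.1
        w_pkg = _enet_solve(X, y, lam, 0.5, tol=1e-10, max_iter=100000)
        w_ora = enet_coordinate_descent(X, y, lam, 0.5)
        f_pkg = elastic_net_objective(X, y, w_pkg, lam, 0.5)
        f_ora = elastic_net_objective(X, y, w_ora, lam, 0.5)
        assert abs(f_pkg - f_ora) <= 1e-6 * max(abs(f_ora), 1e-12)

    def test_ridge_closed_form_alpha_zero(self, rng):
        n, p = 25, 6
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        w = _enet_solve(X, y, 0.3, 0.0, tol=1e-10, max_iter=1000)
        A = X.T @ X / n + 0.3 * np.eye(p)
        np.testing.assert_allclose(A @ w, X.T @ y / n, atol=1e-10)

    def test_determinism(self, rng):
        n, p = 40, 15
        X = rng.standard_normal((n, p))
        ages = 70 + X[:, 0] * 2 + rng.normal(0, 1, n)
        cfg = bg.FitConfig(n_folds=4, n_repeats=3, n_lambda=20, seed=7)
        r1 = bg.BrainAgeModel(X, ages, cfg).fit()
        r2 = bg.BrainAgeModel(X, ages, cfg).fit()
        assert r1.lambda_per_repeat == r2.lambda_per_repeat
        assert np.array_equal(r1.weights, r2.weights)

    def test_too_few_subjects_proposes_smaller_folds(self, rng):
        X = rng.standard_normal((12, 4))
        ages = rng.uniform(60, 80, 12)
        with pytest.raises(ValueError, match="n_folds"):
            bg.BrainAgeModel(X, ages, bg.FitConfig(n_folds=10)).fit()

    def test_constant_age_rejected(self, rng):
        X = rng.standard_normal((30, 4))
        with pytest.raises(ValueError, match="constant|variance"):
            bg.BrainAgeModel(X, np.full(30, 70.0), bg.FitConfig(n_folds=3))

    def test_lambda_selected_is_mean_of_repeats(self, rng):
        n, p = 40, 10
        X = rng.standard_normal((n, p))
        ages = 70 + X[:, 1] * 2 + rng.normal(0, 1, n)
        cfg = bg.FitConfig(n_folds=4, n_repeats=3, n_lambda=15, seed=5)
        res = bg.BrainAgeModel(X, ages, cfg).fit()
        assert res.lambda_selected == pytest.approx(
            np.mean(res.lambda_per_repeat), abs=0)

    def test_constant_voxels_dropped(self, rng):
        n = 30
        ages = rng.uniform(60, 85, n)
        X = np.column_stack([ages, np.full(n, 0.7), rng.standard_normal(n)])
        cfg = bg.FitConfig(n_folds=3, n_repeats=1, n_lambda=10, seed=6)
        res = bg.BrainAgeModel(X, ages, cfg).fit()
        assert res.weights[1] == 0.0


class TestLambdaSelection:
    def test_zero_se_returns_lambda_min(self):
        curve = pd.DataFrame({"lambda": [1.0, 0.5, 0.1],
                              "mean_error": [1.0, 2.0, 3.0],
                              "se": [0.0, 0.0, 0.0]})
        # error strictly increases as lambda decreases -> min at lambda=1.0
        assert bg.select_lambda_1se(curve) == 1.0
        curve2 = pd.DataFrame({"lambda": [1.0, 0.5, 0.1],
                               "mean_error": [3.0, 2.0, 1.0],
                               "se": [0.0, 0.0, 0.0]})
        assert bg.select_lambda_1se(curve2) == 0.1

    def test_hand_evaluated_case(self):
        curve = pd.DataFrame({"lambda": [1.0, 0.5, 0.1],
                              "mean_error": [2.0, 1.6, 1.5],
                              "se": [0.5, 0.3, 0.3]})
        # threshold = 1.5 + 0.3 = 1.8; eligible {0.5, 0.1}; max -> 0.5
        assert bg.select_lambda_1se(curve) == 0.5

    def test_single_eligible(self):
        curve = pd.DataFrame({"lambda": [1.0, 0.1],
                              "mean_error": [10.0, 1.0],
                              "se": [0.1, 0.1]})
        assert bg.select_lambda_1se(curve) == 0.1

    def test_all_nan_curve_errors(self):
        curve = pd.DataFrame({"lambda": [1.0, 0.1],
                              "mean_error": [np.nan, np.nan],
                              "se": [0.1, 0.1]})
        with pytest.raises(ValueError):
            bg.select_lambda_1se(curve)

    def test_auto_grid_top_kills_all_coefficients(self, rng):
        n, p = 30, 10
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        grid = auto_lambda_grid(Xs, yc, 0.5, n_lambda=10)
        w = _enet_solve(Xs, yc, grid[0], 0.5, tol=1e-10, max_iter=10000)
        assert np.count_nonzero(w) == 0


class TestPredict:
    def test_zero_weight_model_predicts_intercept(self, rng):
        n, p = 40, 10
        X = rng.standard_normal((n, p))
        ages = rng.uniform(60, 80, n)
        Xs = (X - X.mean(0)) / X.std(0)
        lam_max = float(np.max(np.abs(Xs.T @ (ages - ages.mean()))) / (n * 0.5))
        cfg = bg.FitConfig(n_folds=4, n_repeats=1,
                           lambda_grid=[3 * lam_max, 2 * lam_max], seed=1)
        res = bg.BrainAgeModel(X, ages, cfg).fit()
        pred = res.predict(rng.standard_normal((5, p)))
        np.testing.assert_allclose(pred, res.intercept, atol=1e-10)

    def test_hand_built_arithmetic(self, rng):
        # w = (1, 0, 0), intercept 50, feature 20 -> prediction 70
        n = 30
        X = rng.standard_normal((n, 3))
        ages = rng.uniform(60, 80, n)
        cfg = bg.FitConfig(n_folds=3, n_repeats=1, n_lambda=5, seed=0)
        res = bg.BrainAgeModel(X, ages, cfg).fit()
        res.weights = np.array([1.0, 0.0, 0.0])
        res.intercept = 50.0
        assert res.predict(np.array([[20.0, 5.0, -3.0]]))[0] == pytest.approx(70.0)

    def test_voxel_index_mismatch_rejected(self, template16, rng):
        mask = bg.build_mask(template16.data, 0.1)
        vols = bg.simulate_gm_cohort(
            template16, np.zeros_like(template16.data), 30, (60, 85),
            0.02, 0, 72.0, seed=4)
        design = bg.vectorize(vols, mask)
        cfg = bg.FitConfig(n_folds=3, n_repeats=1, n_lambda=5, seed=0)
        res = bg.BrainAgeModel(design, config=cfg).fit()
        other_mask = bg.build_mask(template16.data, 0.3)
        other = bg.vectorize(vols, other_mask)
        with pytest.raises(ValueError, match="voxel_index|mask"):
            res.predict(other)

    def test_in_sample_predictions_self_consistent(self, rng):
        n, p = 40, 12
        X = rng.standard_normal((n, p))
        ages = 70 + X[:, 0] * 2 + rng.normal(0, 1, n)
        cfg = bg.FitConfig(n_folds=4, n_repeats=2, n_lambda=15, seed=9)
        model = bg.BrainAgeModel(X, ages, cfg)
        res = model.fit()
        np.testing.assert_allclose(res.fitted_values(),
                                   res.intercept + X @ res.weights, atol=1e-8)


class TestBiasCorrection:
    def test_unbiased_model_gives_zero_coefficients(self, rng):
        ages = rng.uniform(60, 90, 50)
        bias = bg.fit_bias_correction(ages.copy(), ages)
        assert bias.slope_a == pytest.approx(0.0, abs=1e-12)
        assert bias.intercept_b == pytest.approx(0.0, abs=1e-10)

    def test_deterministic_line_closed_form(self, rng):
        ages = rng.uniform(60, 90, 50)
        pred = 0.5 * ages + 40
        bias = bg.fit_bias_correction(pred, ages)
        assert bias.slope_a == pytest.approx(-0.5, abs=1e-10)
        assert bias.intercept_b == pytest.approx(40.0, abs=1e-8)

    def test_constant_offset(self, rng):
        ages = rng.uniform(60, 90, 50)
        bias = bg.fit_bias_correction(ages + 2.0, ages)
        assert bias.slope_a == pytest.approx(0.0, abs=1e-12)
        assert bias.intercept_b == pytest.approx(2.0, abs=1e-10)

    def test_noop_correction(self, rng):
        ages = rng.uniform(60, 90, 20)
        pred = ages + rng.normal(0, 2, 20)
        tab = bg.apply_bias_correction(pred, ages, bg.BiasCorrection(0.0, 0.0))
        np.testing.assert_allclose(tab["bag"], pred - ages)
        np.testing.assert_allclose(tab["pred_corrected"] - tab["age"],
                                   tab["bag"], atol=0)

    def test_exact_cancellation_on_own_line(self, rng):
        ages = rng.uniform(60, 90, 30)
        pred = 0.5 * ages + 40
        bias = bg.fit_bias_correction(pred, ages)
        tab = bg.apply_bias_correction(pred, ages, bias)
        np.testing.assert_allclose(tab["bag"], 0.0, atol=1e-9)

    def test_post_correction_identity(self, rng):
        # residual orthogonality: corrected BAG has no linear age trend
        ages = rng.uniform(55, 90, 100)
        pred = 25 + 0.6 * ages + rng.normal(0, 3, 100)
        bias = bg.fit_bias_correction(pred, ages)
        tab = bg.apply_bias_correction(pred, ages, bias)
        slope, intercept = np.polyfit(ages, tab["bag"], 1)
        assert abs(slope) < 1e-8 and abs(intercept) < 1e-8

    def test_degenerate_age_variance_rejected(self):
        with pytest.raises(ValueError):
            bg.fit_bias_correction(np.array([70.0, 71, 72]),
                                   np.array([70.0, 70, 70]))


class TestEvaluate:
    def test_perfect_prediction_flags_undefined_r(self):
        ages = np.array([70.0, 75.0, 80.0])
        m = bg.evaluate(ages.copy(), ages)
        assert m.mae == 0 and m.rmse == 0
        assert m.r_defined  # both vectors vary; r is defined and 1
        assert m.pearson_r == pytest.approx(1.0)
        m2 = bg.evaluate(np.full(3, 75.0), ages)
        assert not m2.r_defined and np.isnan(m2.pearson_r)

    def test_hand_arithmetic(self):
        ages = np.array([1.0, 2.0])
        m = bg.evaluate(ages + np.array([1.0, -1.0]), ages)
        assert m.mae == pytest.approx(1.0) and m.rmse == pytest.approx(1.0)
        ages3 = np.array([1.0, 2.0, 3.0])
        m3 = bg.evaluate(ages3 + np.array([0.0, 0.0, 3.0]), ages3)
        assert m3.mae == pytest.approx(1.0)
        assert m3.rmse == pytest.approx(np.sqrt(3.0))

    @given(st.integers(0, 2**31 - 1))
    def test_mae_never_exceeds_rmse(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 50))
        pred = r.normal(70, 10, n)
        ages = r.normal(70, 10, n)
        m = bg.evaluate(pred, ages)
        assert m.mae <= m.rmse + 1e-12


class TestSerialization:
    def test_save_and_reuse_weights(self, template16, tmp_path, rng):
        mask = bg.build_mask(template16.data, 0.1)
        w = bg.make_signal_map(template16, 2, 0.004, seed=1)
        vols = bg.simulate_gm_cohort(template16, w, 30, (60, 85), 0.02, 2.0,
                                     72.0, seed=4)
        design = bg.vectorize(vols, mask)
        cfg = bg.FitConfig(n_folds=3, n_repeats=1, n_lambda=10, seed=0)
        res = bg.BrainAgeModel(design, config=cfg).fit()
        res.save(tmp_path, mask=mask)
        import json
        meta = json.loads((tmp_path / "model.json").read_text())
        assert meta["alpha"] == 0.5
        arr = np.loadtxt(tmp_path / "weights.csv", delimiter=",", skiprows=1)
        pred = meta["intercept"] + design.values @ arr[:, 1]
        np.testing.assert_allclose(pred, res.fitted_values(), atol=1e-8)
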