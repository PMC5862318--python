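import numpy as np
import pandas as pd
import pytest

from unprofit.learners import (
    AnovaRegressionTree,
    LearnerSpec,
    MeanRegressor,
    RidgeLOOCV,
    default_library,
    fit_learner,
    make_estimator,
    predict_learner,
)


def orthonormal_design(n=64, p=8, seed=0):
    """Columns orthonormal and orthogonal to the intercept (mean zero)."""
    rng = np.random.default_rng(seed)
    M = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    Q, _ = np.linalg.qr(M)
    X = Q[:, 1:]  # orthonormal, each column mean ~0
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])


def soft_threshold(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


class TestSpecs:
    def test_ids_follow_field_naming(self):
        assert LearnerSpec("linear_main_terms", "full").id == "glm.f"
        assert LearnerSpec("neural_net_2unit", "groups").id == "nnet.g"
        assert LearnerSpec("lasso_cv", "screened").id == "lasso.l"

    def test_default_library_is_five_by_three(self):
        lib = default_library()
        ids = [s.id for s in lib]
        assert len(lib) == 15
        assert len(set(ids)) == 15

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            LearnerSpec("random_forest", "full")


class TestLinear:
    def test_interpolates_noiseless_linear_data(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.integers(0, 2, (60, 6)).astype(float),
                         columns=[f"x{j}" for j in range(6)])
        beta = rng.normal(0, 1000, 6)
        y = X.to_numpy() @ beta + 50.0
        fit = fit_learner(LearnerSpec("linear_main_terms", "full"), X, y)
        np.testing.assert_allclose(predict_learner(fit, X), y, atol=1e-6)

    def test_collinear_columns_resolved(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 50).astype(float)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.integers(0, 2, 50).astype(float)})
        y = 100 * a + 5 * X["c"].to_numpy()
        fit = fit_learner(LearnerSpec("linear_main_terms", "full"), X, y)
        np.testing.assert_allclose(predict_learner(fit, X), y, atol=1e-6)


class TestRidge:
    def test_closed_form_on_orthonormal_design(self):
        X = orthonormal_design()
        rng = np.random.default_rng(3)
        y = rng.normal(0, 10, len(X))
        for alpha in (0.1, 1.0, 10.0):
            est = RidgeLOOCV(alphas=np.array([alpha])).fit(X.to_numpy(), y)
            yc = y - y.mean()
            # centered orthonormal Gram is the identity:
            # beta = X^T y_c / (1 + alpha)
            expected = X.to_numpy().T @ yc / (1.0 + alpha)
            np.testing.assert_allclose(est.coef_, expected, atol=1e-8)

    def test_small_penalty_converges_to_ols(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.5, 80)
        ridge = RidgeLOOCV(alphas=np.array([1e-10])).fit(X, y)
        ols = np.linalg.lstsq(np.column_stack([np.ones(80), X]), y, rcond=None)[0]
        np.testing.assert_allclose(ridge.coef_, ols[1:], atol=1e-5)
        np.testing.assert_allclose(ridge.intercept_, ols[0], atol=1e-5)

    def test_matches_sklearn_loo_selection(self):
        from sklearn.linear_model import RidgeCV

        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 1, 120)
        grid = np.logspace(-2, 3, 11)
        ours = RidgeLOOCV(alphas=grid).fit(X, y)
        ref = RidgeCV(alphas=grid).fit(X, y)
        assert ours.alpha_ == pytest.approx(ref.alpha_)
        np.testing.assert_allclose(ours.coef_, ref.coef_, atol=1e-8)


class TestLasso:
    def test_soft_threshold_closed_form_on_orthonormal_design(self):
        X = orthonormal_design(seed=7)
        rng = np.random.default_rng(7)
        y = rng.normal(0, 5, len(X))
        alpha = 0.05
        spec = LearnerSpec("lasso_cv", "full", hyperparameters=(("alphas", [alpha]),))
        fit = fit_learner(spec, X, y)
        n = len(X)
        z = X.to_numpy().T @ (y - y.mean())
        # sklearn objective (1/2n)||y - Xb||^2 + alpha |b|  =>  soft(z, n*alpha)
        expected = soft_threshold(z, n * alpha)
        np.testing.assert_allclose(fit.estimator.coef_, expected, atol=1e-6)

    def test_fully_penalized_predicts_intercept(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.integers(0, 2, (40, 4)).astype(float),
                         columns=list("abcd"))
        y = rng.normal(1000, 100, 40)
        spec = LearnerSpec("lasso_cv", "full", hyperparameters=(("alphas", [1e12]),))
        fit = fit_learner(spec, X, y)
        np.testing.assert_allclose(predict_learner(fit, X), y.mean(), rtol=1e-6)

    def test_active_set_non_increasing_in_penalty(self):
        from sklearn.linear_model import lasso_path

        rng = np.random.default_rng(9)
        X = (rng.random((200, 20)) < 0.3).astype(float)
        y = X[:, :5] @ np.arange(1, 6) * 100.0 + rng.normal(0, 50, 200)
        alphas, coefs, _ = lasso_path(X - X.mean(0), y - y.mean(), alphas=50)
        sizes = (coefs != 0).sum(axis=0)  # alphas descending
        # at grid resolution the active set grows as the penalty shrinks
        assert np.all(np.diff(sizes) >= 0)


class TestTree:
    def test_first_split_matches_exhaustive_variance_search(self):
        rng = np.random.default_rng(10)
        X = (rng.random((500, 6)) < 0.5).astype(float)
        y = 2000.0 * X[:, 3] + rng.normal(0, 100, 500)
        est = AnovaRegressionTree().fit(X, y)

        def sse_reduction(j):
            left, right = y[X[:, j] == 0], y[X[:, j] == 1]
            if len(left) == 0 or len(right) == 0:
                return -np.inf
            total = ((y - y.mean()) ** 2).sum()
            return total - ((left - left.mean()) ** 2).sum() - ((right - right.mean()) ** 2).sum()

        oracle = max(range(6), key=sse_reduction)
        assert est.tree_.tree_.feature[0] == oracle == 3

    def test_step_function_gives_fold_constant_predictions(self):
        X = pd.DataFrame({"x": np.repeat([0.0, 1.0], 50)})
        y = np.where(X["x"] == 1, 5000.0, 0.0)
        fit = fit_learner(LearnerSpec("regression_tree_anova", "full"), X, y)
        pred = predict_learner(fit, X)
        assert set(np.round(pred, 6)) == {0.0, 5000.0}

    def test_cp_blocks_weak_splits(self):
        rng = np.random.default_rng(11)
        X = (rng.random((300, 3)) < 0.5).astype(float)
        y = rng.normal(0, 1, 300)  # pure noise: no split clears cp
        est = AnovaRegressionTree(cp=0.01).fit(X, y)
        assert est.tree_.get_depth() == 0


class TestNeuralNet:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame((rng.random((120, 5)) < 0.4).astype(float),
                         columns=[f"x{j}" for j in range(5)])
        y = 300 * X["x0"].to_numpy() + rng.normal(0, 10, 120)
        spec = LearnerSpec("neural_net_2unit", "full")
        p1 = predict_learner(fit_learner(spec, X, y, seed=42), X)
        p2 = predict_learner(fit_learner(spec, X, y, seed=42), X)
        np.testing.assert_array_equal(p1, p2)

    def test_predictions_on_dollar_scale(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame((rng.random((200, 3)) < 0.5).astype(float),
                         columns=list("abc"))
        y = 10_000 + 5_000 * X["a"].to_numpy() + rng.normal(0, 200, 200)
        fit = fit_learner(LearnerSpec("neural_net_2unit", "full"), X, y, seed=1)
        pred = predict_learner(fit, X)
        assert abs(pred.mean() - y.mean()) < 2_000  # back-transform sanity


class TestContract:
    def test_constant_outcome_falls_back_to_mean(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0]})
        with pytest.warns(UserWarning, match="constant outcome"):
            fit = fit_learner(LearnerSpec("lasso_cv", "full"), X, np.full(4, 7.0))
        assert fit.fallback
        np.testing.assert_allclose(predict_learner(fit, X), 7.0)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame((rng.random((150, 4)) < 0.5).astype(float),
                         columns=list("abcd"))
        y = X.to_numpy() @ np.array([10.0, -5.0, 3.0, 0.0]) + rng.normal(0, 1, 150)
        shuffled = X[["c", "a", "d", "b"]]
        for alg in ("linear_main_terms", "ridge_cv", "lasso_cv",
                    "regression_tree_anova", "neural_net_2unit"):
            fit = fit_learner(LearnerSpec(alg, "full"), X, y, seed=3)
            np.testing.assert_allclose(
                predict_learner(fit, X), predict_learner(fit, shuffled), rtol=1e-10,
                err_msg=alg,
            )

    def test_column_mismatch_names_offenders(self):
        X = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
        fit = fit_learner(LearnerSpec("linear_main_terms", "full"), X, np.array([1.0, 2.0]))
        bad = pd.DataFrame({"a": [0.0], "z": [1.0]})
        with pytest.raises(ValueError, match="z"):
            predict_learner(fit, bad)

    def test_mean_regressor(self):
        est = MeanRegressor().fit(np.zeros((3, 2)), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(est.predict(np.zeros((5, 2))), 2.0)
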