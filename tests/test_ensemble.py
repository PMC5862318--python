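import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from unprofit import (
    SuperLearnerRegressor,
    assign_folds,
    cv_predictions,
    estimate_weights,
)
from unprofit.ensemble import FoldAssignment
from unprofit.learners import LearnerSpec


def grid_search_simplex(U, Z, step):
    """Dense grid oracle for the simplex-constrained least squares."""
    K = Z.shape[1]
    best, best_alpha = np.inf, None
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for combo in itertools.product(ticks, repeat=K - 1):
        if sum(combo) > 1.0 + 1e-12:
            continue
        alpha = np.array(list(combo) + [1.0 - sum(combo)])
        obj = float(np.sum((U - Z @ alpha) ** 2))
        if obj < best:
            best, best_alpha = obj, alpha
    return best_alpha, best


MEAN_TREE = LearnerSpec("regression_tree_anova", "full",
                        hyperparameters=(("cp", 1e12),))  # never splits


class TestFolds:
    def test_n_equal_v_gives_singletons(self):
        fa = assign_folds(10, 10, seed=1)
        assert sorted(np.bincount(fa.labels)) == [1] * 10

    def test_balanced_sizes_95_by_10(self):
        fa = assign_folds(95, 10, seed=2)
        sizes = sorted(np.bincount(fa.labels))
        assert sizes == [9] * 5 + [10] * 5

    def test_deterministic(self):
        np.testing.assert_array_equal(
            assign_folds(50, 5, seed=3).labels, assign_folds(50, 5, seed=3).labels
        )

    def test_v_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(5, 6)
        with pytest.raises(ValueError):
            assign_folds(5, 1)


class TestCVPredictions:
    def test_mean_learner_reproduces_out_of_fold_means(self):
        # 12-row fixture, 3 known folds; a never-splitting tree predicts the
        # training mean, so Z must equal each row's out-of-fold mean
        y = np.arange(12, dtype=float) * 10
        X = pd.DataFrame({"a": np.tile([0.0, 1.0], 6)})
        labels = np.repeat([0, 1, 2], 4)
        folds = FoldAssignment(labels=labels, V=3)
        Z = cv_predictions([MEAN_TREE], X, y, folds, {"full": ("a",)}).Z
        for v in range(3):
            expected = y[labels != v].mean()
            np.testing.assert_allclose(Z[labels == v, 0], expected)

    def test_no_leakage_of_own_outcome(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame((rng.random((60, 4)) < 0.5).astype(float), columns=list("abcd"))
        y = X["a"].to_numpy() * 100 + rng.normal(0, 10, 60)
        folds = assign_folds(60, 5, seed=5)
        spec = [LearnerSpec("linear_main_terms", "full")]
        vsets = {"full": tuple("abcd")}
        Z1 = cv_predictions(spec, X, y, folds, vsets).Z
        y2 = y.copy()
        y2[17] += 1e8
        Z2 = cv_predictions(spec, X, y2, folds, vsets).Z
        np.testing.assert_array_equal(Z1[17], Z2[17])

    def test_dimensions(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame((rng.random((30, 3)) < 0.5).astype(float), columns=list("abc"))
        y = rng.normal(size=30)
        folds = assign_folds(30, 3, seed=6)
        specs = [LearnerSpec("linear_main_terms", "full"), MEAN_TREE]
        Z = cv_predictions(specs, X, y, folds, {"full": tuple("abc")})
        assert Z.Z.shape == (30, 2)
        assert Z.learner_ids == ("glm.f", "tree.f")


class TestWeights:
    def test_single_learner_forced_to_one(self):
        U = np.array([1.0, 2.0, 3.0])
        w = estimate_weights(U, U.reshape(-1, 1) * 0.5)
        np.testing.assert_array_equal(w.alpha, [1.0])

    def test_perfect_column_takes_all_weight(self):
        rng = np.random.default_rng(7)
        U = rng.normal(0, 100, 400)
        Z = np.column_stack([U, rng.normal(0, 100, 400)])
        w = estimate_weights(U, Z)
        grid_alpha, _ = grid_search_simplex(U, Z, step=1e-3)
        assert np.max(np.abs(w.alpha - grid_alpha)) <= 2e-3
        assert w.alpha[0] > 0.99

    @pytest.mark.parametrize("K,seed", [(2, 0), (2, 1), (3, 2), (3, 3)])
    def test_matches_grid_search_on_small_problems(self, K, seed):
        rng = np.random.default_rng(seed)
        n = 30
        U = rng.normal(0, 10, n)
        Z = np.column_stack(
            [0.3 * U + rng.normal(0, 6, n) for _ in range(K)]
        )
        w = estimate_weights(U, Z)
        step = 1e-3 if K == 2 else 5e-3
        grid_alpha, grid_obj = grid_search_simplex(U, Z, step=step)
        ours = float(np.sum((U - Z @ w.alpha) ** 2))
        assert ours <= grid_obj + 1e-9  # at least as good as the best grid point
        assert np.max(np.abs(w.alpha - grid_alpha)) <= step + 1e-3

    def test_simplex_constraints_hold(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            U = rng.normal(0, 5, 50)
            Z = rng.normal(0, 5, (50, 6))
            w = estimate_weights(U, Z)
            assert np.all(w.alpha >= 0)
            assert abs(w.alpha.sum() - 1.0) < 1e-10

    def test_never_worse_than_any_vertex(self):
        rng = np.random.default_rng(9)
        U = rng.normal(0, 5, 80)
        Z = np.column_stack([U + rng.normal(0, s, 80) for s in (1.0, 3.0, 10.0)])
        w = estimate_weights(U, Z)
        n = len(U)
        for k in range(3):
            vertex_obj = float(np.mean((U - Z[:, k]) ** 2))
            assert w.objective <= vertex_obj + 1e-9

    def test_identical_columns_give_uniform_weights(self):
        U = np.arange(20, dtype=float)
        Z = np.tile(U.reshape(-1, 1) * 0.9, (1, 4))
        with pytest.warns(UserWarning, match="identical"):
            w = estimate_weights(U, Z)
        np.testing.assert_allclose(w.alpha, 0.25)


class TestSuperLearner:
    def make_data(self, n=200, seed=10):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame((rng.random((n, 5)) < 0.4).astype(float),
                         columns=[f"x{j}" for j in range(5)])
        y = X.to_numpy() @ np.array([2000.0, -1000.0, 500.0, 0.0, 0.0])
        return X, y + rng.normal(0, 100, n)

    def test_default_library_has_fifteen_learners_and_ten_folds(self):
        sl = SuperLearnerRegressor()
        assert len(sl._resolved_library()) == 15
        assert sl.V == 10

    def test_degenerate_weight_equals_single_learner(self):
        X, y = self.make_data()
        y_exact = X.to_numpy() @ np.array([2000.0, -1000.0, 500.0, 0.0, 0.0])
        lib = [LearnerSpec("linear_main_terms", "full"), MEAN_TREE]
        sl = SuperLearnerRegressor(library=lib, V=5, forced=(), random_state=1).fit(X, y_exact)
        assert sl.alpha_[0] == pytest.approx(1.0, abs=1e-6)
        glm_only = sl.predict_candidates(X)[:, 0]
        np.testing.assert_allclose(sl.predict(X), glm_only, rtol=1e-10)

    def test_prediction_within_candidate_envelope(self):
        X, y = self.make_data(seed=11)
        lib = [LearnerSpec("linear_main_terms", "full"),
               LearnerSpec("regression_tree_anova", "full"),
               LearnerSpec("ridge_cv", "full")]
        sl = SuperLearnerRegressor(library=lib, V=5, forced=(), random_state=2).fit(X, y)
        cand = sl.predict_candidates(X)
        pred = sl.predict(X)
        assert np.all(pred <= cand.max(axis=1) + 1e-9)
        assert np.all(pred >= cand.min(axis=1) - 1e-9)

    def test_bit_reproducible_from_seed(self):
        X, y = self.make_data(seed=12)
        lib = [LearnerSpec("linear_main_terms", "full"),
               LearnerSpec("neural_net_2unit", "full")]
        a = SuperLearnerRegressor(library=lib, V=4, forced=(), random_state=3).fit(X, y)
        b = SuperLearnerRegressor(library=lib, V=4, forced=(), random_state=3).fit(X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        np.testing.assert_array_equal(a.alpha_, b.alpha_)

    def test_sklearn_params_and_clone(self):
        sl = SuperLearnerRegressor(V=7, screen_cap=4)
        assert sl.get_params()["V"] == 7
        cloned = clone(sl)
        assert cloned.get_params()["screen_cap"] == 4

    def test_screened_learners_share_fold_screen_and_refit_screens_full(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame((rng.random((300, 8)) < 0.4).astype(float),
                         columns=[f"x{j}" for j in range(8)])
        y = X["x2"].to_numpy() * 4000 + rng.normal(0, 100, 300)
        lib = [LearnerSpec("linear_main_terms", "screened"),
               LearnerSpec("lasso_cv", "screened")]
        sl = SuperLearnerRegressor(library=lib, V=3, screen_cap=2,
                                   forced=("x7",), random_state=4).fit(X, y)
        assert set(sl.cv_matrix_.fold_screened) == {0, 1, 2}
        for vs in sl.cv_matrix_.fold_screened.values():
            assert "x7" in vs.columns and len(vs.columns) <= 3
        assert sl.screened_full_ is not None
        assert "x2" in sl.screened_full_.columns
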