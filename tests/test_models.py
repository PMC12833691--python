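"""OLS, conditional inference tree and random forest model families."""

import numpy as np
import pytest

from opineq import cit_test, evaluate, fit_cit, fit_forest, fit_linear, tune_depth


# ---------------------------------------------------------------------------
# brute-force oracle for the conditional inference tree root decision
# ---------------------------------------------------------------------------

def brute_force_root(X, y, min_leaf):
    """Exhaustive root split: variable with max |Pearson r|, split point
    maximising the naive two-sample standardized statistic, ties -> smallest c."""
    n, k = X.shape
    rs = [abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(k)]
    j_star = int(np.argmax(rs))
    ybar, syy = y.mean(), np.sum((y - y.mean()) ** 2)
    xs = np.unique(X[:, j_star])
    best_c, best_z = None, -np.inf
    for a, b in zip(xs[:-1], xs[1:]):
        c = (a + b) / 2
        left = X[:, j_star] <= c
        nl = int(left.sum())
        if nl < min_leaf or n - nl < min_leaf:
            continue
        var = nl * (n - nl) / (n * (n - 1)) * syy
        z = abs(y[left].sum() - nl * ybar) / np.sqrt(var)
        if z > best_z + 1e-12:
            best_c, best_z = c, z
    return j_star, best_c


class TestLinear:
    def test_noiseless_perfect_fit(self, rng):
        X = rng.standard_normal((100, 3))
        y = 2 + X @ np.array([1.0, -2.0, 0.5])
        m = fit_linear(X, y)
        assert m.diagnostics["train_r2"] == pytest.approx(1.0)
        assert np.allclose(m.fitted, y)

    def test_two_group_closed_form(self):
        # binary regressor with group means 2 and 4: slope 2, intercept 2
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([1.0, 3.0, 3.0, 5.0])
        m = fit_linear(X, y)
        assert m.coef_ == pytest.approx([2.0, 2.0])

    def test_permutation_invariance(self, rng):
        X = rng.standard_normal((80, 4))
        y = X @ rng.standard_normal(4) + rng.standard_normal(80)
        perm = rng.permutation(80)
        a = fit_linear(X, y)
        b = fit_linear(X[perm], y[perm])
        assert np.allclose(a.coef_, b.coef_)

    def test_collinear_column_named(self, rng):
        import pandas as pd
        X = pd.DataFrame({"a": rng.standard_normal(50)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(X, rng.standard_normal(50))

    def test_predict_new_rows(self, rng):
        X = rng.standard_normal((100, 2))
        y = 1 + X[:, 0]
        m = fit_linear(X, y)
        Xn = rng.standard_normal((5, 2))
        assert np.allclose(m.predict(Xn), 1 + Xn[:, 0], atol=1e-8)


class TestCitTest:
    def test_identical_variable_tiny_p(self, rng):
        y = rng.standard_normal(100)
        assert cit_test(y, y) < 1e-20

    def test_constant_variable_p_one(self, rng):
        assert cit_test(np.ones(50), rng.standard_normal(50)) == 1.0

    def test_permutation_mode_agrees_roughly(self, rng):
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        p_asym = cit_test(x, y)
        p_perm = cit_test(x, y, method="permutation", n_perm=4999,
                          rng=np.random.default_rng(0))
        assert p_perm == pytest.approx(p_asym, abs=0.02)

    def test_type_one_error_calibration(self):
        # asymptotic p-values approximately uniform under independence
        hits = 0
        n_rep = 400
        for s in range(n_rep):
            r = np.random.default_rng(s)
            hits += cit_test(r.standard_normal(80), r.standard_normal(80)) < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)


class TestFitCit:
    def test_depth_zero_single_leaf_grand_mean(self, rng):
        X = rng.standard_normal((100, 2))
        y = X[:, 0] + rng.standard_normal(100)
        m = fit_cit(X, y, max_depth=0)
        assert m.root.is_leaf
        assert np.allclose(m.fitted, y.mean())

    def test_step_function_recovered(self, rng):
        X = rng.uniform(-1, 1, (500, 3))
        y = (X[:, 0] > 0).astype(float) + 0.1 * rng.standard_normal(500)
        m = fit_cit(X, y)
        assert m.root.feature == 0
        assert abs(m.root.threshold) < 0.1

    @pytest.mark.parametrize("seed", range(8))
    def test_root_agrees_with_exhaustive_oracle(self, seed):
        r = np.random.default_rng(seed)
        n, k = int(r.integers(25, 51)), int(r.integers(1, 4))
        X = r.standard_normal((n, k))
        beta = r.uniform(0.5, 1.5, k) * r.choice([-1, 1], k)
        y = X @ beta + 0.5 * r.standard_normal(n)
        min_leaf = 5
        j_oracle, c_oracle = brute_force_root(X, y, min_leaf)
        m = fit_cit(X, y, max_depth=1, min_node=10, min_leaf=min_leaf)
        assert not m.root.is_leaf
        assert m.root.feature == j_oracle
        assert m.root.threshold == pytest.approx(c_oracle)

    def test_pure_noise_mostly_single_leaf(self):
        leaves = sum(
            fit_cit(np.random.default_rng(s).standard_normal((150, 3)),
                    np.random.default_rng(s + 10_000).standard_normal(150)).root.is_leaf
            for s in range(60))
        assert leaves >= 50  # ~95% expected at alpha = 0.05

    def test_predictions_are_leaf_means(self, rng):
        X = rng.uniform(-1, 1, (300, 2))
        y = (X[:, 0] > 0) * 2.0 + rng.standard_normal(300) * 0.2
        m = fit_cit(X, y, max_depth=1)
        left = X[:, 0] <= m.root.threshold
        assert np.allclose(m.fitted[left], y[left].mean())
        assert np.allclose(m.fitted[~left], y[~left].mean())


class TestForest:
    def test_prediction_is_mean_of_trees(self, rng):
        X = rng.standard_normal((200, 4))
        y = X[:, 0] * X[:, 1] + 0.2 * rng.standard_normal(200)
        m = fit_forest(X, y, n_trees=25, seed=0)
        per_tree = np.mean([t.predict(X) for t in m.sk_model.estimators_], axis=0)
        assert np.allclose(per_tree, m.fitted, atol=1e-12)

    def test_single_tree_no_bootstrap_equals_cart(self, rng):
        from sklearn.tree import DecisionTreeRegressor
        X = rng.standard_normal((150, 3))
        y = (X[:, 0] > 0) + 0.1 * rng.standard_normal(150)
        m = fit_forest(X, y, n_trees=1, max_features=3, bootstrap=False,
                       min_leaf=5, seed=0)
        cart = DecisionTreeRegressor(min_samples_leaf=5, random_state=0).fit(X, y)
        assert np.allclose(m.fitted, cart.predict(X))

    def test_oob_excludes_uncovered_rows_with_warning(self, rng):
        X = rng.standard_normal((60, 2))
        y = rng.standard_normal(60)
        with pytest.warns(UserWarning, match="never out of bag"):
            m = fit_forest(X, y, n_trees=2, seed=0)
        assert m.diagnostics["oob_n"] < 60

    def test_oob_tracks_test_mse(self, rng):
        X = rng.standard_normal((1200, 5))
        y = X[:, 0] * X[:, 1] + 0.5 * rng.standard_normal(1200)
        m = fit_forest(X[:800], y[:800], n_trees=150, seed=1)
        test = evaluate(m, X[800:], y[800:])
        assert m.diagnostics["oob_error"] == pytest.approx(test["mse"], rel=0.3)

    def test_interaction_beats_linear(self, rng):
        X = rng.standard_normal((2000, 5))
        y = X[:, 0] * X[:, 1] + 0.5 * rng.standard_normal(2000)
        lin = fit_linear(X[:1500], y[:1500])
        rf = fit_forest(X[:1500], y[:1500], n_trees=100, max_depth=8, seed=2)
        assert (evaluate(rf, X[1500:], y[1500:])["r2"]
                > evaluate(lin, X[1500:], y[1500:])["r2"])


class TestTuneDepthEvaluate:
    def test_two_split_dgp_needs_depth_two(self, rng):
        X = rng.uniform(-1, 1, (800, 2))
        y = ((X[:, 0] > 0) & (X[:, 1] > 0)) * 2.0 + 0.2 * rng.standard_normal(800)
        depth = tune_depth("cit", X, y, grid=[1, 2, 3, 4], seed=0)
        assert depth >= 2

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((400, 3))
        y = X[:, 0] + 0.5 * rng.standard_normal(400)
        a = tune_depth("forest", X, y, grid=[1, 2, 3], seed=5, n_trees=20)
        b = tune_depth("forest", X, y, grid=[1, 2, 3], seed=5, n_trees=20)
        assert a == b

    def test_evaluate_toy_values(self):
        class Const:
            def predict(self, X):
                return np.array([1.0, 2.0, 4.0])
        out = evaluate(Const(), np.zeros((3, 1)), np.array([1.0, 2.0, 3.0]))
        assert out["mse"] == pytest.approx(1 / 3)
        assert out["r2"] == pytest.approx(0.5)

    def test_perfect_and_mean_predictions(self, rng):
        y = rng.standard_normal(50)

        class Echo:
            def predict(self, X):
                return y
        assert evaluate(Echo(), np.zeros((50, 1)), y) == {"mse": 0.0, "r2": 1.0}

        class Mean:
            def predict(self, X):
                return np.full(50, y.mean())
        assert evaluate(Mean(), np.zeros((50, 1)), y)["r2"] == pytest.approx(0.0)

    def test_constant_test_response_warns_nan(self, rng):
        class Z:
            def predict(self, X):
                return np.zeros(10)
        with pytest.warns(UserWarning, match="constant"):
            out = evaluate(Z(), np.zeros((10, 1)), np.ones(10))
        assert np.isnan(out["r2"])
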