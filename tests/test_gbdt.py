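import math

import numpy as np
import pytest

from seqboost.errors import DegenerateLabelsError, ShapeError
from seqboost.gbdt import (
    fit_tree,
    init_score,
    leaf_values,
    logistic_loss,
    model_from_json,
    model_to_json,
    predict,
    predict_proba,
    predict_score,
    pseudo_residuals,
    train,
)


def grid_leaf_oracle(y_pm, h, lo=-4.0, hi=4.0, step=1e-4):
    """Brute-force 1-D minimizer of sum log(1+exp(-y(h+v)))."""
    grid = np.arange(lo, hi + step, step)
    losses = [
        np.sum(np.log1p(np.exp(-y_pm * (h + v)))) for v in grid
    ]
    return grid[int(np.argmin(losses))]


class TestInitScore:
    def test_balanced(self):
        assert init_score(np.array([1, 1, 0, 0])) == 0.0

    def test_three_to_one(self):
        assert init_score(np.array([1, 1, 1, 0])) == pytest.approx(0.5 * math.log(3))

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            init_score(np.ones(4))


class TestPseudoResiduals:
    def test_at_zero_score(self):
        assert pseudo_residuals(np.array([1.0]), np.array([0.0]))[0] == 0.5
        assert pseudo_residuals(np.array([-1.0]), np.array([0.0]))[0] == -0.5

    def test_saturation(self):
        r = pseudo_residuals(np.array([1.0]), np.array([200.0]))
        assert r[0] == pytest.approx(0.0, abs=1e-20)

    def test_matches_negative_gradient_numerically(self, rng):
        """r_i == -dF/dh via central finite differences."""
        y_pm = np.where(rng.random(20) < 0.5, -1.0, 1.0)
        h = rng.normal(size=20)
        eps = 1e-6
        for i in range(20):
            up, down = h.copy(), h.copy()
            up[i] += eps
            down[i] -= eps
            grad = (
                np.log1p(np.exp(-y_pm[i] * up[i])) - np.log1p(np.exp(-y_pm[i] * down[i]))
            ) / (2 * eps)
            assert pseudo_residuals(y_pm, h)[i] == pytest.approx(-grad, abs=1e-6)


class TestFitTree:
    def test_constant_residuals_single_leaf(self):
        X = np.arange(8.0)[:, None]
        tree, assign = fit_tree(X, np.full(8, 0.3), max_depth=3, min_leaf=1)
        assert tree.n_leaves == 1
        assert np.unique(assign).size == 1

    def test_obvious_split(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        r = np.array([-1.0, -1.0, 1.0, 1.0])
        tree, _ = fit_tree(X, r, max_depth=1, min_leaf=1)
        assert tree.feature[0] == 0
        assert tree.threshold[0] == pytest.approx(2.5)

    def test_exhaustive_gain_enumeration(self, rng):
        """Chosen split must equal the argmax over all (feature, midpoint)
        candidates of the squared-error reduction."""
        X = rng.normal(size=(30, 3))
        r = rng.normal(size=30)
        tree, _ = fit_tree(X, r, max_depth=1, min_leaf=2)
        best_gain, best = -np.inf, None
        base = r.sum() ** 2 / r.size
        for j in range(3):
            xs = np.sort(np.unique(X[:, j]))
            for lo, hi in zip(xs[:-1], xs[1:]):
                thr = (lo + hi) / 2
                left = r[X[:, j] <= thr]
                right = r[X[:, j] > thr]
                if len(left) < 2 or len(right) < 2:
                    continue
                gain = left.sum() ** 2 / len(left) + right.sum() ** 2 / len(right) - base
                if gain > best_gain + 1e-12:
                    best_gain, best = gain, (j, thr)
        assert (tree.feature[0], tree.threshold[0]) == pytest.approx(best)

    def test_duplicate_rows_leaf_mean(self):
        X = np.array([[1.0], [1.0], [5.0], [5.0]])
        r = np.array([0.2, 0.4, 1.0, 2.0])
        tree, assign = fit_tree(X, r, max_depth=1, min_leaf=1)
        values = np.array(tree.value)[assign]
        assert values[0] == pytest.approx(0.3)
        assert values[2] == pytest.approx(1.5)


class TestLeafValues:
    def test_single_positive_first_newton_step(self):
        """From v=0 with y=+1, h=0: r=0.5, hess=0.25 -> first step 2."""
        y_pm = np.array([1.0])
        h = np.array([0.0])
        v0, step = 0.0, 0.5 / (0.5 * 0.5)
        assert v0 + step == 2.0
        # full Newton solution matches the grid oracle (minimum clipped at 4:
        # a lone positive drives v to the +4 clip)
        X = np.array([[0.0]])
        tree, assign = fit_tree(X, np.array([0.5]), max_depth=1, min_leaf=1)
        tree = leaf_values(tree, assign, y_pm, h)
        assert tree.value[assign[0]] == pytest.approx(4.0)

    def test_symmetric_pair_gives_zero(self):
        X = np.zeros((2, 1))
        y_pm = np.array([1.0, -1.0])
        h = np.zeros(2)
        tree, assign = fit_tree(X, pseudo_residuals(y_pm, h), max_depth=1, min_leaf=1)
        tree = leaf_values(tree, assign, y_pm, h)
        assert tree.value[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_newton_matches_grid_oracle(self, seed):
        local = np.random.default_rng(seed)
        y_pm = np.where(local.random(12) < 0.6, 1.0, -1.0)
        if np.unique(y_pm).size < 2:
            y_pm[0] = -y_pm[0]
        h = local.normal(scale=0.5, size=12)
        X = np.zeros((12, 1))
        tree, assign = fit_tree(X, pseudo_residuals(y_pm, h), max_depth=1, min_leaf=1)
        tree = leaf_values(tree, assign, y_pm, h)
        oracle = grid_leaf_oracle(y_pm, h)
        assert tree.value[0] == pytest.approx(oracle, abs=1e-3)


class TestTrain:
    def test_loss_monotone_on_separable_data(self):
        X = np.arange(20.0)[:, None]
        y = (X[:, 0] >= 10).astype(int)
        model = train(X, y, rounds=20, lr=0.1, max_depth=1, min_leaf=1)
        diffs = np.diff(model.loss_curve)
        assert np.all(diffs <= 1e-9)
        assert model.loss_curve[-1] < model.loss_curve[0]

    def test_zero_rounds_predicts_prevalence(self, rng):
        y = np.array([1, 1, 1, 0])
        X = rng.normal(size=(4, 2))
        model = train(X, y, rounds=0)
        proba = predict_proba(model, rng.normal(size=(5, 2)))
        assert np.allclose(proba, 0.75)

    def test_deterministic(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, size=40)
        a = train(X, y, rounds=8, seed=1)
        b = train(X, y, rounds=8, seed=1)
        assert a.loss_curve == b.loss_curve
        pa = predict_proba(a, X)
        pb = predict_proba(b, X)
        assert np.array_equal(pa, pb)

    def test_loss_non_increasing_random_labels(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, size=60)
        model = train(X, y, rounds=25, lr=0.3)
        assert np.all(np.diff(model.loss_curve) <= 1e-9)

    def test_single_leaf_trees_converge_to_loss_optimum(self, rng):
        """J=1 reduces to iterated scalar Newton on a global constant score;
        the limit score is the closed-form minimizer of the logistic loss,
        the full log-odds lambda = log(n_pos/n_neg), so every prediction
        converges to sigmoid(2*lambda)."""
        X = rng.normal(size=(40, 2))
        y = (rng.random(40) < 0.3).astype(int)
        log_odds = math.log(y.sum() / (len(y) - y.sum()))
        expected = 1 / (1 + math.exp(-2 * log_odds))
        model = train(X, y, rounds=200, lr=0.5, max_depth=0, min_leaf=40)
        proba = predict_proba(model, X)
        assert np.allclose(proba, expected, atol=1e-6)

    def test_shrinkage_consistency(self, rng):
        """Doubling rounds and halving lr barely moves held-out AUC."""
        from seqboost.evaluation import roc_auc

        X = rng.normal(size=(300, 6))
        beta = np.array([1.5, -1.0, 0.8, 0.0, 0.0, 0.0])
        y = (X @ beta + 0.5 * rng.normal(size=300) > 0).astype(int)
        X_tr, y_tr, X_te, y_te = X[:200], y[:200], X[200:], y[200:]
        a = train(X_tr, y_tr, rounds=40, lr=0.2)
        b = train(X_tr, y_tr, rounds=80, lr=0.1)
        auc_a = roc_auc(y_te, predict_proba(a, X_te))
        auc_b = roc_auc(y_te, predict_proba(b, X_te))
        assert abs(auc_a - auc_b) < 0.02


class TestPredict:
    def test_monotone_link(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        model = train(X, y, rounds=5)
        h = predict_score(model, X)
        p = predict_proba(model, X)
        order = np.argsort(h)
        assert np.all(np.diff(p[order]) >= 0)

    def test_threshold(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        model = train(X, y, rounds=3)
        assert np.array_equal(predict(model, X), (predict_proba(model, X) >= 0.5).astype(int))

    def test_dimension_mismatch(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        model = train(X, y, rounds=2)
        with pytest.raises(ShapeError):
            predict_proba(model, rng.normal(size=(5, 4)))


def test_agreement_with_reference_implementation(rng):
    """Held-out AUC within 0.03 of scikit-learn's gradient boosting with
    matched hyperparameters on the same synthetic problem."""
    from sklearn.ensemble import GradientBoostingClassifier

    from seqboost.evaluation import roc_auc

    X = rng.normal(size=(500, 8))
    beta = np.array([1.2, -0.9, 0.7, 0.5, 0, 0, 0, 0])
    y = (X @ beta + rng.normal(size=500) > 0).astype(int)
    X_tr, y_tr, X_te, y_te = X[:350], y[:350], X[350:], y[350:]
    ours = train(X_tr, y_tr, rounds=60, lr=0.1, max_depth=3, min_leaf=5)
    ref = GradientBoostingClassifier(
        n_estimators=60, learning_rate=0.1, max_depth=3, min_samples_leaf=5,
        random_state=0,
    ).fit(X_tr, y_tr)
    auc_ours = roc_auc(y_te, predict_proba(ours, X_te))
    auc_ref = roc_auc(y_te, ref.predict_proba(X_te)[:, 1])
    assert abs(auc_ours - auc_ref) < 0.03


def test_json_round_trip(tmp_path, rng):
    X = rng.normal(size=(30, 3))
    y = rng.integers(0, 2, size=30)
    y[:2] = [0, 1]
    model = train(X, y, rounds=5)
    path = tmp_path / "model.json"
    model_to_json(model, path)
    back = model_from_json(path)
    assert np.array_equal(predict_proba(model, X), predict_proba(back, X))


def test_logistic_loss_at_zero():
    assert logistic_loss(np.array([1.0, -1.0]), np.zeros(2)) == pytest.approx(math.log(2))
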