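"""Boosted-tree tests: exhaustive split oracle, boosting invariants, LOO."""

import json

import numpy as np
import pandas as pd
import pytest

from nanohisto import gtb
from nanohisto.gtb import (
    GTBConfig,
    GTBModel,
    TreeNode,
    feature_importance,
    fit,
    loo_cv,
    predict,
    r_squared,
    training_mse_path,
)
from nanohisto.scoring import ValidationError


# ---------------------------------------------------------------------------
# independent oracle: naive exhaustive-enumeration regression tree
# ---------------------------------------------------------------------------

def _naive_sse(vals):
    vals = np.asarray(vals, dtype=float)
    return float(np.sum((vals - vals.mean()) ** 2)) if len(vals) else 0.0


def _naive_priority(X, y):
    """|corr(feature, outcome)| over observed rows, computed with plain sums."""
    pri = []
    for f in range(X.shape[1]):
        pairs = [(X[i, f], y[i]) for i in range(len(y))
                 if not np.isnan(X[i, f])]
        if len(pairs) < 2:
            pri.append(0.0)
            continue
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
        sxx = sum((a - mx) ** 2 for a in xs)
        syy = sum((b - my) ** 2 for b in ys)
        if sxx == 0 or syy == 0:
            pri.append(0.0)
            continue
        sxy = sum((a - mx) * (b - my) for a, b in pairs)
        pri.append(abs(sxy / (sxx * syy) ** 0.5))
    return pri


def _oracle_tree(X, y, depth, max_depth, min_leaf=1, priority=None):
    """Plain-loop variance-reduction tree mirroring the documented rules:
    midpoint thresholds, missing rows excluded from statistics and routed to
    the lower-SSE side (ties left), equal-loss split ties resolved toward
    the feature most correlated with the residuals (then lowest index,
    lowest threshold)."""
    y = np.asarray(y, dtype=float)
    if priority is None:
        priority = _naive_priority(X, y)
    if depth >= max_depth or len(y) < 2:
        return ("leaf", float(y.mean()))
    parent = _naive_sse(y)
    best = None
    for f in range(X.shape[1]):
        xf = X[:, f]
        obs = sorted(set(xf[~np.isnan(xf)]))
        for lo, hi in zip(obs, obs[1:]):
            thr = (lo + hi) / 2
            for default_left in (True, False):
                left = [i for i in range(len(y))
                        if (np.isnan(xf[i]) and default_left)
                        or (not np.isnan(xf[i]) and xf[i] < thr)]
                right = [i for i in range(len(y)) if i not in left]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                sse = _naive_sse(y[left]) + _naive_sse(y[right])
                if best is None or sse < best[0] - 1e-12:
                    best = (sse, f, thr, default_left, left, right)
                elif (sse <= best[0] + 1e-12
                      and priority[f] > priority[best[1]] + 1e-12):
                    best = (sse, f, thr, default_left, left, right)
    if best is None or best[0] >= parent - 1e-12:
        return ("leaf", float(y.mean()))
    _, f, thr, dl, left, right = best
    return ("split", f, thr, dl,
            _oracle_tree(X[left], y[left], depth + 1, max_depth, min_leaf,
                         priority),
            _oracle_tree(X[right], y[right], depth + 1, max_depth, min_leaf,
                         priority))


def _oracle_predict(node, row):
    while node[0] == "split":
        _, f, thr, dl, left, right = node
        x = row[f]
        if np.isnan(x):
            node = left if dl else right
        else:
            node = left if x < thr else right
    return node[1]


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------

class TestFit:
    def test_constant_outcome_gives_splitless_model(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        model = fit(X, np.full(4, 7.5), GTBConfig())
        assert model.base_prediction == 7.5
        assert all(t.is_leaf for t in model.trees)
        np.testing.assert_allclose(predict(model, X), 7.5)

    def test_binary_feature_exact_single_split(self):
        X = pd.DataFrame({"b": [0.0, 0.0, 1.0, 1.0]})
        y = np.array([0.0, 0.0, 10.0, 10.0])
        model = fit(X, y, GTBConfig(n_trees=1, max_depth=1, learning_rate=1.0))
        np.testing.assert_allclose(predict(model, X), y)

    def test_missing_cell_routed_to_loss_minimizing_default(self):
        X = pd.DataFrame({"b": [np.nan, 0.0, 1.0, 1.0]})
        y = np.array([0.0, 0.0, 10.0, 10.0])
        model = fit(X, y, GTBConfig(n_trees=1, max_depth=1, learning_rate=1.0))
        # enumerating both default directions: sending the missing sample
        # left reproduces the clean fit's zero loss, so left must be learned
        root = model.trees[0]
        assert not root.is_leaf and root.default_left
        np.testing.assert_allclose(predict(model, X), y)

    def test_missing_outcome_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            fit(X, np.array([1.0, np.nan]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            fit(pd.DataFrame({"a": [1.0]}), np.array([1.0]))

    @pytest.mark.parametrize("seed", range(30))
    def test_single_tree_matches_exhaustive_oracle(self, seed):
        """On small datasets (<= 6 samples, <= 3 features, with missing
        cells) a one-tree fit equals the naive enumeration oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        p = int(rng.integers(1, 4))
        depth = int(rng.integers(1, 4))
        X = rng.uniform(0, 1, size=(n, p))
        X[rng.uniform(size=X.shape) < 0.15] = np.nan
        y = rng.uniform(0, 10, size=n)
        model = fit(pd.DataFrame(X), y,
                    GTBConfig(n_trees=1, max_depth=depth, learning_rate=1.0))
        # boosting on residuals with lr=1 and one tree reduces to the plain
        # regression tree on y itself (leaf mean shifts cancel)
        oracle = _oracle_tree(X, y, 0, depth)
        expected = np.array([_oracle_predict(oracle, X[i]) for i in range(n)])
        np.testing.assert_allclose(predict(model, pd.DataFrame(X)), expected,
                                   atol=1e-9)

    def test_single_tree_matches_oracle_on_exhaustive_binary_designs(self):
        """Every binary 4-sample, 2-feature design with integer outcomes."""
        y = np.array([0.0, 1.0, 3.0, 2.0])
        for bits in range(256):
            X = np.array([[(bits >> (2 * i + j)) & 1 for j in range(2)]
                          for i in range(4)], dtype=float)
            model = fit(pd.DataFrame(X), y,
                        GTBConfig(n_trees=1, max_depth=2, learning_rate=1.0))
            oracle = _oracle_tree(X, y, 0, 2)
            expected = np.array([_oracle_predict(oracle, X[i])
                                 for i in range(4)])
            np.testing.assert_allclose(predict(model, pd.DataFrame(X)),
                                       expected, atol=1e-9)


class TestPredict:
    def test_empty_tree_list_returns_base(self):
        model = GTBModel(base_prediction=4.2, trees=[], config=GTBConfig(),
                         feature_names=["a"])
        np.testing.assert_allclose(predict(model, np.array([[1.0], [2.0]])),
                                   4.2)

    def test_all_missing_row_follows_default_paths(self):
        # manually assembled 2-tree model; trace default directions by hand
        t1 = TreeNode(feature=0, threshold=0.5, default_left=True,
                      left=TreeNode(value=2.0), right=TreeNode(value=9.0))
        t2 = TreeNode(feature=1, threshold=0.3, default_left=False,
                      left=TreeNode(value=-1.0), right=TreeNode(value=1.5))
        model = GTBModel(base_prediction=1.0, trees=[t1, t2],
                         config=GTBConfig(learning_rate=0.5),
                         feature_names=["a", "b"])
        row = np.array([[np.nan, np.nan]])
        # base + lr*(left of t1 + right of t2) = 1 + 0.5*(2.0 + 1.5)
        assert predict(model, row)[0] == pytest.approx(2.75)

    def test_schema_mismatch_rejected(self):
        model = GTBModel(base_prediction=0.0, trees=[], config=GTBConfig(),
                         feature_names=["a", "b"])
        with pytest.raises(ValidationError):
            predict(model, pd.DataFrame({"a": [1.0]}))
        with pytest.raises(ValidationError):
            predict(model, np.zeros((2, 3)))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.uniform(size=(10, 4)),
                         columns=["a", "b", "c", "d"])
        y = rng.uniform(size=10)
        model = fit(X, y, GTBConfig(n_trees=3, max_depth=3))
        perm = X[["c", "a", "d", "b"]]
        model_p = fit(perm, y, GTBConfig(n_trees=3, max_depth=3))
        np.testing.assert_allclose(predict(model, X), predict(model_p, perm),
                                   atol=1e-9)
        rep = feature_importance([model]).to_frame().set_index("feature")
        rep_p = feature_importance([model_p]).to_frame().set_index("feature")
        for name in "abcd":
            assert rep.loc[name, "mean_importance"] == pytest.approx(
                rep_p.loc[name, "mean_importance"])


class TestBoostingInvariants:
    @pytest.mark.parametrize("lr", [0.1, 0.3, 1.0])
    def test_training_mse_monotone_in_tree_count(self, lr):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(12, 4)))
        y = rng.normal(size=12)
        path = training_mse_path(X, y, GTBConfig(n_trees=8, learning_rate=lr))
        assert np.all(np.diff(path) <= 1e-10)

    def test_depth_bound_respected(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.uniform(size=(30, 3)))
        y = rng.uniform(size=30)
        model = fit(X, y, GTBConfig(n_trees=2, max_depth=3))

        def depth(node):
            return 0 if node.is_leaf else 1 + max(depth(node.left),
                                                  depth(node.right))

        assert all(depth(t) <= 3 for t in model.trees)

    def test_complete_data_predictions_ignore_default_machinery(self):
        """With no missing cells, traversal must never consult the stored
        default directions."""
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.uniform(size=(12, 3)))
        y = rng.uniform(size=12)
        model = fit(X, y, GTBConfig(n_trees=4, max_depth=4))

        def strict_traverse(node, row):
            while not node.is_leaf:
                node = node.left if row[node.feature] < node.threshold else node.right
            return node.value

        lr = model.config.learning_rate
        Xm = X.to_numpy()
        manual = model.base_prediction + lr * np.array(
            [sum(strict_traverse(t, Xm[i]) for t in model.trees)
             for i in range(len(Xm))])
        np.testing.assert_allclose(predict(model, X), manual, atol=1e-12)


class TestLOO:
    def test_fold_structure(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        y = np.array([0.0, 1.0, 2.0])
        res = loo_cv(X, y, GTBConfig(n_trees=1, max_depth=1))
        assert len(res.fold_models) == 3
        assert len(res.predicted) == 3

    def test_no_information_leak(self):
        """Altering sample i's outcome never changes its own LOO prediction."""
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.uniform(size=(8, 3)))
        y = rng.uniform(size=8)
        base = loo_cv(X, y, GTBConfig(n_trees=2, max_depth=2))
        y2 = y.copy()
        y2[3] += 100.0
        leaked = loo_cv(X, y2, GTBConfig(n_trees=2, max_depth=2))
        assert leaked.predicted[3] == pytest.approx(base.predicted[3])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            loo_cv(pd.DataFrame({"a": [1.0, 2.0]}), np.array([1.0, 2.0]))


class TestImportance:
    def _model_with_counts(self, counts):
        """Ensemble whose split counts per feature are as given."""
        trees = []
        for f, k in enumerate(counts):
            for _ in range(k):
                trees.append(TreeNode(feature=f, threshold=0.5,
                                      default_left=True,
                                      left=TreeNode(value=0.0),
                                      right=TreeNode(value=1.0)))
        return GTBModel(base_prediction=0.0, trees=trees, config=GTBConfig(),
                        feature_names=[f"f{i}" for i in range(len(counts))])

    def test_single_feature_dominates(self):
        rep = feature_importance([self._model_with_counts([4, 0])])
        assert rep.mean_importance[0] == pytest.approx(1.0)
        assert rep.mean_importance[1] == pytest.approx(0.0)

    def test_three_to_one_split_ratio(self):
        rep = feature_importance([self._model_with_counts([3, 1])])
        np.testing.assert_allclose(rep.mean_importance, [0.75, 0.25])
        assert rep.ranking == ["f0", "f1"]

    def test_fold_importances_sum_to_one(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.uniform(size=(10, 4)))
        y = rng.uniform(size=10)
        res = loo_cv(X, y, GTBConfig(n_trees=3, max_depth=3))
        rep = feature_importance(res.fold_models)
        assert rep.mean_importance.sum() == pytest.approx(1.0)
        assert np.all(rep.sd_importance >= 0)

    def test_splitless_ensembles_flagged(self):
        model = GTBModel(base_prediction=1.0, trees=[TreeNode(value=0.0)],
                         config=GTBConfig(), feature_names=["a"])
        rep = feature_importance([model])
        assert rep.no_splits
        np.testing.assert_allclose(rep.mean_importance, 0.0)


class TestRSquared:
    def test_perfect_and_affine_prediction(self):
        m = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(m, m) == pytest.approx(1.0)
        assert r_squared(m, 3 * m - 2) == pytest.approx(1.0)

    def test_matches_hand_computed_pearson(self):
        m = np.array([1.0, 2.0, 4.0, 5.0])
        p = np.array([1.5, 1.0, 3.0, 6.0])
        cov = np.mean((m - m.mean()) * (p - p.mean()))
        expected = (cov / (m.std() * p.std())) ** 2
        assert r_squared(m, p) == pytest.approx(expected)

    def test_determination_option(self):
        m = np.array([1.0, 2.0, 3.0])
        p = np.array([1.0, 2.0, 4.0])
        expected = 1 - 1.0 / np.sum((m - 2.0) ** 2)
        assert r_squared(m, p, method="determination") == pytest.approx(expected)

    def test_constant_measured_rejected(self):
        with pytest.raises(ValidationError):
            r_squared([1.0, 1.0], [0.0, 1.0])


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.uniform(size=(10, 3)), columns=["a", "b", "c"])
        y = rng.uniform(size=10)
        model = fit(X, y, GTBConfig(n_trees=3, max_depth=3))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = GTBModel.from_json(path)
        assert loaded.feature_names == ["a", "b", "c"]
        np.testing.assert_allclose(predict(loaded, X), predict(model, X))
        json.loads(path.read_text())  # valid JSON document
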