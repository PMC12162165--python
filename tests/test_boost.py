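"""Boosted-tree core: gradients, leaf weights, split search, training.

The split search is validated against exhaustive enumeration of every
(feature, threshold) candidate, and whole-model behaviour against an
independent reference gradient-boosting implementation.
"""

import numpy as np
import pandas as pd
import pytest

from specklenose.boost import (
    DegenerateLeafError,
    Ensemble,
    GBTParams,
    fit,
    fit_arrays,
    grow_tree,
    leaf_weight,
    predict_labels,
    predict_proba,
    softmax_grad_hess,
    split_gain,
    structure_score,
)


class TestSoftmaxGradHess:
    def test_uniform_scores_five_classes(self):
        gh = softmax_grad_hess(np.array([0]), np.zeros((1, 5)))
        np.testing.assert_allclose(gh.g[0], [-0.8, 0.2, 0.2, 0.2, 0.2], atol=1e-12)
        np.testing.assert_allclose(gh.h[0], [0.16] * 5, atol=1e-12)

    def test_saturated_true_class_has_vanishing_gradient(self):
        raw = np.array([[50.0, 0.0, 0.0]])
        gh = softmax_grad_hess(np.array([0]), raw)
        assert np.abs(gh.g).max() < 1e-12
        assert np.all(gh.h >= 0)

    def test_matches_finite_differences(self):
        """g and h agree with numerical derivatives of the log-loss."""
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(6, 4))
        labels = rng.integers(0, 4, size=6)

        def loss(scores):
            z = scores - scores.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            return -logp[np.arange(len(labels)), labels].sum()

        gh = softmax_grad_hess(labels, raw)
        eps = 1e-5
        for i in range(raw.shape[0]):
            for c in range(raw.shape[1]):
                up, dn = raw.copy(), raw.copy()
                up[i, c] += eps
                dn[i, c] -= eps
                g_num = (loss(up) - loss(dn)) / (2 * eps)
                h_num = (loss(up) - 2 * loss(raw) + loss(dn)) / eps**2
                assert gh.g[i, c] == pytest.approx(g_num, abs=1e-5)
                assert gh.h[i, c] == pytest.approx(h_num, abs=1e-4)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(FloatingPointError):
            softmax_grad_hess(np.array([0]), np.array([[np.inf, 0.0]]))


class TestLeafWeight:
    def test_zero_gradient_zero_weight(self):
        assert leaf_weight(0.0, 5.0, 1.0) == 0.0

    def test_direct_arithmetic(self):
        assert leaf_weight(2.0, 3.0, 1.0) == pytest.approx(-0.5)

    def test_squared_error_leaf_recovers_mean(self):
        """For squared error with targets {1,2,3}: g_i=-y_i, h_i=1, so the
        analytic w* is the mean; check against 1-D grid minimization of
        the second-order objective."""
        targets = np.array([1.0, 2.0, 3.0])
        g = -targets
        h = np.ones(3)
        w_star = leaf_weight(g.sum(), h.sum(), 0.0)
        assert w_star == pytest.approx(2.0)
        grid = np.linspace(-5, 5, 100001)
        obj = g.sum() * grid + 0.5 * h.sum() * grid**2
        assert grid[np.argmin(obj)] == pytest.approx(w_star, abs=1e-4)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(DegenerateLeafError):
            leaf_weight(1.0, 0.0, 0.0)


class TestStructureScore:
    def test_single_leaf(self):
        score = structure_score(np.zeros(3), np.array([-2.0, -2.0, -2.0]),
                                np.array([1.0, 1.0, 1.0]), 0.0, 0.0)
        assert score == pytest.approx(-6.0)

    def test_gamma_adds_per_leaf(self):
        score = structure_score(np.zeros(3), np.array([-2.0, -2.0, -2.0]),
                                np.array([1.0, 1.0, 1.0]), 0.0, 1.0)
        assert score == pytest.approx(-5.0)

    def test_empty_leaf_rejected(self):
        with pytest.raises(DegenerateLeafError):
            structure_score(np.array([0, 0]), np.array([1.0, 1.0]),
                            np.array([1.0, 1.0]), 0.0, 0.0, n_leaves=2)

    def test_parent_minus_children_equals_split_gain(self):
        """On an 8-instance toy, score(parent) - score(children) matches
        split_gain for every binary split of every feature."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        g = rng.normal(size=8)
        h = rng.uniform(0.5, 2.0, size=8)
        lam, gamma = 1.0, 0.3
        parent = structure_score(np.zeros(8), g, h, lam, gamma)
        for j in range(2):
            for thr in np.unique(X[:, j])[:-1] + 1e-9:
                left = X[:, j] < thr
                if left.all() or not left.any():
                    continue
                children = structure_score(left.astype(int), g, h, lam, gamma)
                gain = split_gain(g[left].sum(), h[left].sum(),
                                  g[~left].sum(), h[~left].sum(), lam, gamma)
                assert parent - children == pytest.approx(gain, abs=1e-10)


def brute_force_best_split(X, g, h, params):
    """Exhaustive enumeration of all (feature, midpoint) candidates."""
    best = None
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (a + b)
            left = X[:, j] < thr
            HL, HR = h[left].sum(), h[~left].sum()
            if HL < params.min_child_hessian or HR < params.min_child_hessian:
                continue
            gain = split_gain(g[left].sum(), HL, g[~left].sum(), HR,
                              params.lambda_reg, params.gamma)
            if gain > 0 and (best is None or gain > best[0] + 1e-12):
                best = (gain, j, thr)
    return best


def walk_internal_nodes(tree, X, idx=None, node=0):
    """Yield (node, instance subset) for every internal node."""
    idx = np.arange(X.shape[0]) if idx is None else idx
    if tree.feature[node] < 0:
        return
    yield node, idx
    mask = X[idx, tree.feature[node]] < tree.threshold[node]
    yield from walk_internal_nodes(tree, X, idx[mask], tree.left[node])
    yield from walk_internal_nodes(tree, X, idx[~mask], tree.right[node])


class TestGrowTree:
    def test_perfect_split_depth_one(self):
        X = np.linspace(0, 1, 10).reshape(-1, 1)
        g = np.where(X[:, 0] < 0.5, -1.0, 1.0)
        h = np.ones(10)
        tree = grow_tree((g, h), X, GBTParams(max_depth=1, lambda_reg=0.0))
        assert tree.feature[0] == 0
        left_max = X[X[:, 0] < 0.5, 0].max()
        right_min = X[X[:, 0] >= 0.5, 0].min()
        assert left_max < tree.threshold[0] <= right_min

    def test_large_gamma_gives_single_leaf(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        g = rng.normal(size=20)
        h = np.ones(20)
        tree = grow_tree((g, h), X, GBTParams(max_depth=4, gamma=1e6))
        assert tree.n_leaves == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_every_node_matches_exhaustive_search(self, seed):
        """Greedy split choice equals brute force at every internal node,
        over random toys with n <= 16, d <= 3, depth <= 2."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 17))
        d = int(rng.integers(1, 4))
        X = np.round(rng.normal(size=(n, d)), 2)
        g = rng.normal(size=n)
        h = rng.uniform(0.1, 1.0, size=n)
        params = GBTParams(max_depth=2, lambda_reg=float(rng.uniform(0, 2)),
                           gamma=float(rng.uniform(0, 0.2)))
        tree = grow_tree((g, h), X, params)
        for node, idx in walk_internal_nodes(tree, X):
            oracle = brute_force_best_split(X[idx], g[idx], h[idx], params)
            assert oracle is not None
            gain, feat, thr = oracle
            left = X[idx, tree.feature[node]] < tree.threshold[node]
            got_gain = split_gain(
                g[idx][left].sum(), h[idx][left].sum(),
                g[idx][~left].sum(), h[idx][~left].sum(),
                params.lambda_reg, params.gamma,
            )
            assert got_gain == pytest.approx(gain, abs=1e-9)

    def test_constant_features_give_single_leaf(self):
        X = np.ones((5, 2))
        tree = grow_tree((np.array([1.0, -1, 1, -1, 1]), np.ones(5)), X, GBTParams())
        assert tree.n_leaves == 1


class TestFit:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-2, 0.5, size=(10, 2)), rng.normal(2, 0.5, size=(10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        ens = fit_arrays(X, y, GBTParams(max_depth=2, n_rounds=10))
        pred = predict_proba(ens, X).argmax(axis=1)
        assert (pred == y).mean() == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_arrays(np.ones((5, 2)), np.zeros(5, dtype=int), GBTParams())

    def test_objective_non_increasing(self, classification_table):
        ens = fit(classification_table, GBTParams(n_rounds=25, max_depth=3),
                  feature_cols=[c for c in classification_table if c != "smell"])
        objectives = [entry["objective"] for entry in ens.train_log]
        assert all(b <= a + 1e-9 for a, b in zip(objectives, objectives[1:]))

    def test_leaf_weights_reproduce_from_stats(self, classification_table):
        """Recomputing -G/(H+lambda) from every stored leaf's (G, H)
        reproduces the stored weight exactly."""
        params = GBTParams(n_rounds=5, max_depth=3)
        ens = fit(classification_table, params,
                  feature_cols=[c for c in classification_table if c != "smell"])
        n_leaves = 0
        for row in ens.trees:
            for tree in row:
                for G, H, w in tree.leaf_weights():
                    assert w == leaf_weight(G, H, params.lambda_reg)
                    n_leaves += 1
        assert n_leaves > 0

    def test_gamma_monotonically_prunes(self, classification_table):
        cols = [c for c in classification_table if c != "smell"]
        leaf_counts = []
        for gamma in (0.0, 0.5, 5.0):
            ens = fit(classification_table, GBTParams(n_rounds=5, max_depth=3, gamma=gamma),
                      feature_cols=cols)
            leaf_counts.append(sum(t.n_leaves for row in ens.trees for t in row))
        assert leaf_counts[0] >= leaf_counts[1] >= leaf_counts[2]

    def test_lambda_shrinks_weights_for_fixed_structure(self):
        for G, H in [(3.0, 1.0), (-2.0, 0.5), (10.0, 4.0)]:
            weights = [abs(leaf_weight(G, H, lam)) for lam in (0.0, 1.0, 10.0)]
            assert weights[0] >= weights[1] >= weights[2]

    def test_row_permutation_invariance(self, classification_table):
        cols = [c for c in classification_table if c != "smell"]
        params = GBTParams(n_rounds=5, max_depth=3)
        a = fit(classification_table, params, feature_cols=cols)
        shuffled = classification_table.sample(frac=1.0, random_state=9)
        b = fit(shuffled, params, feature_cols=cols)
        for row_a, row_b in zip(a.trees, b.trees):
            for ta, tb in zip(row_a, row_b):
                assert ta.feature == tb.feature
                np.testing.assert_allclose(ta.threshold, tb.threshold, atol=1e-12)


class TestPredict:
    def test_empty_ensemble_is_uniform(self):
        ens = Ensemble(trees=[], class_order=["a", "b", "c"],
                       params=GBTParams(), feature_names=["f0"])
        p = predict_proba(ens, np.zeros((4, 1)))
        np.testing.assert_allclose(p, 1 / 3, atol=1e-12)

    def test_probabilities_sum_to_one(self, classification_table):
        cols = [c for c in classification_table if c != "smell"]
        ens = fit(classification_table, GBTParams(n_rounds=5, max_depth=3), feature_cols=cols)
        rng = np.random.default_rng(0)
        p = predict_proba(ens, rng.normal(size=(50, len(cols))))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_schema_mismatch_rejected(self, classification_table):
        cols = [c for c in classification_table if c != "smell"]
        ens = fit(classification_table, GBTParams(n_rounds=2), feature_cols=cols)
        with pytest.raises(ValueError):
            predict_proba(ens, pd.DataFrame({"wrong": [1.0]}))

    def test_json_round_trip(self, classification_table):
        cols = [c for c in classification_table if c != "smell"]
        ens = fit(classification_table, GBTParams(n_rounds=3, max_depth=2), feature_cols=cols)
        back = Ensemble.from_json(ens.to_json())
        X = classification_table[cols].to_numpy()
        np.testing.assert_array_equal(
            predict_proba(ens, X), predict_proba(back, X)
        )


def test_agreement_with_reference_implementation(classification_table):
    """>= 95% label agreement with xgboost under matched hyperparameters
    on the fixed 200-row synthetic table."""
    import xgboost as xgb

    cols = [c for c in classification_table if c != "smell"]
    X = classification_table[cols].to_numpy()
    y = classification_table["smell"].map(
        {c: i for i, c in enumerate(sorted(classification_table["smell"].unique()))}
    ).to_numpy()
    params = GBTParams(eta=0.3, max_depth=3, lambda_reg=1.0, gamma=0.0, n_rounds=20)
    ours = fit_arrays(X, y, params)
    ref = xgb.XGBClassifier(
        n_estimators=params.n_rounds, learning_rate=params.eta,
        max_depth=params.max_depth, reg_lambda=params.lambda_reg,
        gamma=params.gamma, min_child_weight=params.min_child_hessian,
        tree_method="exact", objective="multi:softprob",
        subsample=1.0, colsample_bytree=1.0, base_score=0.5,
    )
    ref.fit(X, y)
    ours_pred = predict_proba(ours, X).argmax(axis=1)
    agreement = (ours_pred == ref.predict(X)).mean()
    assert agreement >= 0.95
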