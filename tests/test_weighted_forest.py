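"""Forest contracts: weighting arithmetic, OOB bookkeeping, importances."""

import numpy as np
import pytest
from dataclasses import replace

from caredemand.weighted_forest import (ForestParams, TreeRecord,
                                        WeightedForest, accuracy_weights,
                                        fit_forest, fit_tree, forest_from_json,
                                        forest_to_json, oob_error,
                                        permutation_importance, predict,
                                        predict_proba)


def separable_data(rng, n=200, p=3):
    X = rng.standard_normal((n, p))
    y = (X[:, 0] >= 0).astype(int)
    return X, y


class TestFitTree:
    def test_pure_labels_single_leaf(self, rng):
        X = rng.standard_normal((30, 2))
        tree = fit_tree(X, np.ones(30, dtype=int), ForestParams(), rng)
        assert (tree.predict(X) == 1).all()
        assert tree.used_features() == set()

    def test_separable_1d_depth_one(self, rng):
        X = np.linspace(-1, 1, 100)[:, None]
        y = (X[:, 0] >= 0).astype(int)
        params = ForestParams(max_depth=1, min_leaf=1, mtry=1)
        tree = fit_tree(X, y, params, rng)
        assert np.mean(tree.predict(X) == y) == 1.0

    def test_matches_reference_cart_accuracy(self, rng):
        """Depth-matched plain CART is the reference on small random data."""
        from sklearn.tree import DecisionTreeClassifier

        for _ in range(5):
            X = rng.standard_normal((80, 4))
            y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.standard_normal(80) > 0).astype(int)
            params = ForestParams(max_depth=4, min_leaf=2, mtry=4)
            tree = fit_tree(X, y, params, rng)
            ref = DecisionTreeClassifier(max_depth=4, min_samples_leaf=2,
                                         random_state=0).fit(X, y)
            acc = np.mean(tree.predict(X) == y)
            assert acc >= ref.score(X, y) - 0.05

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_tree(np.empty((0, 2)), np.empty(0), ForestParams(), rng)


class TestWeights:
    def test_single_tree_weight_one(self, rng):
        X, y = separable_data(rng, n=50)
        forest = fit_forest(X, y, ForestParams(n_trees=1, seed=0))
        assert forest.weights[0] == 1.0

    def test_accuracy_normalization_arithmetic(self):
        np.testing.assert_allclose(accuracy_weights([0.9, 0.6]), [0.6, 0.4])

    def test_weights_sum_to_one(self, rng):
        X, y = separable_data(rng)
        forest = fit_forest(X, y, ForestParams(n_trees=25, seed=1))
        assert forest.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_class_labels_rejected(self, rng):
        X = rng.standard_normal((40, 2))
        with pytest.raises(ValueError):
            fit_forest(X, np.ones(40, dtype=int), ForestParams(n_trees=3))


class TestPrediction:
    def test_unanimous_votes(self, rng):
        X, y = separable_data(rng)
        forest = fit_forest(X, y, ForestParams(n_trees=10, max_depth=6,
                                               min_leaf=1, mtry=3, seed=2))
        x = np.array([[3.0, 0.0, 0.0]])  # far on the positive side
        np.testing.assert_allclose(predict_proba(forest, x), [[0.0, 1.0]], atol=1e-12)

    def test_weighted_vote_arithmetic(self):
        class Stub:
            def __init__(self, cls):
                self.cls = cls

            def predict(self, X):
                return np.full(len(X), self.cls)

        records = (
            TreeRecord(Stub(1), np.empty(0, int), np.empty(0, int), 0.9, 0.6),
            TreeRecord(Stub(0), np.empty(0, int), np.empty(0, int), 0.6, 0.4),
        )
        forest = WeightedForest(records, ForestParams(n_trees=2), n_features=2)
        proba = predict_proba(forest, np.zeros((1, 2)))
        np.testing.assert_allclose(proba, [[0.4, 0.6]])

    def test_equal_accuracy_reduces_to_majority(self, rng):
        X, y = separable_data(rng, n=120)
        forest = fit_forest(X, y, ForestParams(n_trees=15, seed=3))
        flat = tuple(replace(r, weight=1.0 / 15) for r in forest.trees)
        equal = WeightedForest(flat, forest.params, forest.n_features,
                               forest.X, forest.y)
        Xt = rng.standard_normal((50, 3))
        votes = np.stack([r.tree.predict(Xt) for r in forest.trees])
        majority = (votes.mean(axis=0) > 0.5).astype(int)
        np.testing.assert_array_equal(predict(equal, Xt), majority)

    def test_feature_count_mismatch_rejected(self, rng):
        X, y = separable_data(rng)
        forest = fit_forest(X, y, ForestParams(n_trees=3, seed=4))
        with pytest.raises(ValueError, match="features"):
            predict_proba(forest, np.zeros((1, 5)))

    def test_determinism_under_seed(self, rng):
        X, y = separable_data(rng)
        f1 = fit_forest(X, y, ForestParams(n_trees=10, seed=5))
        f2 = fit_forest(X, y, ForestParams(n_trees=10, seed=5))
        np.testing.assert_array_equal(f1.weights, f2.weights)
        Xt = rng.standard_normal((20, 3))
        np.testing.assert_array_equal(predict_proba(f1, Xt), predict_proba(f2, Xt))


class TestOOB:
    def test_per_tree_error_definition(self, rng):
        X, y = separable_data(rng, n=100)
        forest = fit_forest(X, y, ForestParams(n_trees=5, seed=6))
        per_tree, _ = oob_error(forest)
        rec = forest.trees[0]
        manual = np.mean(rec.tree.predict(X[rec.oob_indices]) != y[rec.oob_indices])
        assert per_tree[0] == pytest.approx(manual)
        assert per_tree[0] == pytest.approx(1.0 - rec.oob_accuracy)

    def test_separable_low_aggregate_error(self, rng):
        X, y = separable_data(rng, n=1000)
        forest = fit_forest(X, y, ForestParams(n_trees=60, max_depth=10,
                                               min_leaf=1, seed=7))
        _, aggregate = oob_error(forest)
        assert aggregate <= 0.05

    def test_more_trees_do_not_hurt(self, rng):
        from caredemand import generate_cohort, standard_cohort_config
        table = generate_cohort(standard_cohort_config(1000, seed=17))
        X = table.drop(columns="label").to_numpy()
        y = table["label"].to_numpy()
        _, err_small = oob_error(fit_forest(X, y, ForestParams(n_trees=50, seed=8)))
        _, err_large = oob_error(fit_forest(X, y, ForestParams(n_trees=500, seed=8)))
        assert err_large <= err_small + 0.02


class TestPermutationImportance:
    def test_unused_feature_importance_exactly_zero(self, rng):
        X = rng.standard_normal((300, 4))
        X[:, 3] = 0.0  # constant column: never split on
        y = (X[:, 0] > 0).astype(int)
        forest = fit_forest(X, y, ForestParams(n_trees=20, mtry=4, seed=9))
        imp = permutation_importance(forest, n_repeats=2, rng=rng)
        assert imp[3] == 0.0

    def test_planted_feature_beats_noise(self):
        from caredemand import generate_cohort, standard_cohort_config
        wins = 0
        for seed in range(5):
            table = generate_cohort(standard_cohort_config(800, seed=seed))
            X = table.drop(columns="label").to_numpy()
            y = table["label"].to_numpy()
            cols = list(table.columns[:-1])
            forest = fit_forest(X, y, ForestParams(n_trees=60, seed=seed))
            imp = permutation_importance(forest, n_repeats=3,
                                         rng=np.random.default_rng(seed))
            strong = imp[cols.index("chronic_disease_count")]
            noise = max(imp[cols.index(f"noise_{k}")] for k in range(1, 6))
            wins += strong > noise
        assert wins >= 4


def test_json_round_trip_preserves_predictions(rng):
    X, y = separable_data(rng, n=150)
    forest = fit_forest(X, y, ForestParams(n_trees=12, seed=10))
    clone = forest_from_json(forest_to_json(forest))
    Xt = rng.standard_normal((40, 3))
    np.testing.assert_array_equal(predict_proba(forest, Xt),
                                  predict_proba(clone, Xt))
    with pytest.raises(ValueError, match="training data"):
        oob_error(clone)
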