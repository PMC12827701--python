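"""Bagged CART ensemble with out-of-bag accuracy voting weights.

Each tree is fit on an n-of-n bootstrap; the samples a tree never saw
(its out-of-bag set) give a leakage-free per-tree accuracy A_t, and
trees vote with weight

    w_t = A_t / sum_t A_t

on hard class indicators.  The same OOB bookkeeping yields a per-tree
OOB error, an aggregate OOB error of the weighted ensemble, and a
permutation feature importance (mean OOB-error increase when one
feature's values are shuffled within each tree's OOB rows).

Split finding inside each tree is delegated to scikit-learn's CART
(Gini criterion, ``mtry`` features considered per split); the fitted
tree is immediately converted to a flat in-package array form used for
all prediction and serialization, so a saved model has no pickle or
estimator dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ForestParams",
    "TreeRecord",
    "WeightedForest",
    "fit_tree",
    "fit_forest",
    "predict_proba",
    "predict",
    "oob_error",
    "permutation_importance",
    "accuracy_weights",
    "forest_to_json",
    "forest_from_json",
]

CLASSES = np.array([0, 1])


@dataclass(frozen=True)
class ForestParams:
    """Ensemble hyperparameters (defaults: 500 trees, depth 10, leaf 5)."""

    n_trees: int = 500
    max_depth: int = 10
    min_leaf: int = 5
    mtry: int | None = None  # None -> floor(sqrt(n_features))
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.max_depth < 1 or self.min_leaf < 1:
            raise ValueError("n_trees, max_depth and min_leaf must be positive")

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            if not 1 <= self.mtry <= n_features:
                raise ValueError("mtry must lie in [1, n_features]")
            return self.mtry
        return max(1, int(np.sqrt(n_features)))


@dataclass(frozen=True)
class ArrayTree:
    """Flat axis-aligned binary tree; ``children_left == -1`` marks leaves."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        node = np.zeros(X.shape[0], dtype=np.intp)
        while True:
            internal = np.flatnonzero(self.children_left[node] >= 0)
            if internal.size == 0:
                break
            nd = node[internal]
            go_left = X[internal, self.feature[nd]] <= self.threshold[nd]
            node[internal] = np.where(
                go_left, self.children_left[nd], self.children_right[nd]
            )
        return self.leaf_class[node]

    def used_features(self) -> set[int]:
        return set(self.feature[self.children_left >= 0].tolist())


def _from_sklearn(clf: DecisionTreeClassifier, n_features: int) -> ArrayTree:
    t = clf.tree_
    counts = t.value[:, 0, :]  # training sample weight per class per node
    local = np.argmax(counts, axis=1)  # tie -> first class
    leaf_class = np.asarray(clf.classes_, dtype=int)[local]
    return ArrayTree(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        leaf_class=leaf_class,
        n_features=n_features,
    )


@dataclass(frozen=True)
class TreeRecord:
    """One fitted tree with its bootstrap/OOB bookkeeping and weight."""

    tree: ArrayTree
    bootstrap_indices: np.ndarray
    oob_indices: np.ndarray
    oob_accuracy: float
    weight: float = 0.0


@dataclass(frozen=True)
class WeightedForest:
    trees: tuple[TreeRecord, ...]
    params: ForestParams
    n_features: int
    X: np.ndarray | None = None  # training matrix (kept for OOB analyses)
    y: np.ndarray | None = None

    @property
    def weights(self) -> np.ndarray:
        return np.array([rec.weight for rec in self.trees])


def fit_tree(X, y, params: ForestParams, rng: np.random.Generator) -> ArrayTree:
    """Fit one CART (Gini, mtry features per split) and flatten it."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.size == 0 or y.size == 0:
        raise ValueError("empty training data")
    if y.size < 2 * params.min_leaf:
        raise ValueError("need at least 2 * min_leaf samples")
    clf = DecisionTreeClassifier(
        criterion="gini",
        max_depth=params.max_depth,
        min_samples_leaf=params.min_leaf,
        max_features=params.resolved_mtry(X.shape[1]),
        random_state=int(rng.integers(2 ** 31)),
    )
    clf.fit(X, y)
    return _from_sklearn(clf, X.shape[1])


def accuracy_weights(accuracies) -> np.ndarray:
    """Normalize per-tree accuracies into voting weights summing to 1."""
    a = np.asarray(accuracies, dtype=float)
    total = a.sum()
    if total == 0.0:
        return np.full(a.size, 1.0 / a.size)
    return a / total


def fit_forest(X, y, params: ForestParams = ForestParams()) -> WeightedForest:
    """Bootstrap-fit the ensemble and assign OOB-accuracy weights.

    Trees whose OOB set is empty (vanishingly rare at realistic n) get
    the neutral accuracy 0.5 before normalization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with matching y")
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    labels = np.unique(y)
    if not np.isin(labels, CLASSES).all() or labels.size < 2:
        raise ValueError("y must contain both classes 0 and 1")
    rng = np.random.default_rng(params.seed)
    records: list[TreeRecord] = []
    for _ in range(params.n_trees):
        boot = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[boot] = True
        oob = np.flatnonzero(~in_bag)
        tree = fit_tree(X[boot], y[boot], params, rng)
        if oob.size:
            acc = float(np.mean(tree.predict(X[oob]) == y[oob]))
        else:
            acc = 0.5
        records.append(TreeRecord(tree=tree, bootstrap_indices=boot,
                                  oob_indices=oob, oob_accuracy=acc))
    weights = accuracy_weights([r.oob_accuracy for r in records])
    records = [replace(r, weight=float(w)) for r, w in zip(records, weights)]
    return WeightedForest(trees=tuple(records), params=params,
                          n_features=X.shape[1], X=X, y=y)


def predict_proba(forest: WeightedForest, X) -> np.ndarray:
    """Weighted hard-vote class probabilities, shape (n, 2)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != forest.n_features:
        raise ValueError(
            f"expected {forest.n_features} features, got {X.shape[1]}"
        )
    p0 = np.zeros(X.shape[0])
    p1 = np.zeros(X.shape[0])
    for rec in forest.trees:
        votes = rec.tree.predict(X)
        p1 += rec.weight * (votes == 1)
        p0 += rec.weight * (votes == 0)
    # symmetric normalization keeps exact ties at exactly 0.5
    total = p0 + p1
    p0 = np.clip(p0 / total, 0.0, 1.0)
    return np.column_stack([p0, 1.0 - p0])


def predict(forest: WeightedForest, X) -> np.ndarray:
    proba = predict_proba(forest, X)
    return (proba[:, 1] > proba[:, 0]).astype(int)  # tie -> class 0


def _require_training_data(forest: WeightedForest):
    if forest.X is None or forest.y is None:
        raise ValueError("forest was deserialized without its training data; "
                         "OOB analyses need the original (X, y)")
    return forest.X, forest.y


def oob_error(forest: WeightedForest):
    """Per-tree OOB errors and the aggregate weighted-vote OOB error.

    The aggregate scores each training sample with only the trees for
    which it is out of bag (weights renormalized over those trees).
    Returns ``(per_tree, aggregate)``; trees with empty OOB sets report
    NaN and samples never out of bag are excluded from the aggregate.
    """
    X, y = _require_training_data(forest)
    n = y.size
    per_tree = np.full(len(forest.trees), np.nan)
    vote1 = np.zeros(n)
    vote0 = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    any_oob = False
    for t, rec in enumerate(forest.trees):
        if rec.oob_indices.size == 0:
            continue
        any_oob = True
        pred = rec.tree.predict(X[rec.oob_indices])
        per_tree[t] = float(np.mean(pred != y[rec.oob_indices]))
        vote1[rec.oob_indices] += rec.weight * (pred == 1)
        vote0[rec.oob_indices] += rec.weight * (pred == 0)
        covered[rec.oob_indices] = True
    if not any_oob:
        raise ValueError("no tree has out-of-bag samples")
    agg_pred = (vote1[covered] > vote0[covered]).astype(int)
    aggregate = float(np.mean(agg_pred != y[covered]))
    return per_tree, aggregate


def permutation_importance(forest: WeightedForest, n_repeats: int = 5,
                           rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Mean OOB-error increase per feature under within-OOB shuffling.

    For each tree and feature, the feature column is permuted within
    that tree's OOB rows and the tree's OOB error recomputed; the
    importance is the error increase averaged over trees (and over
    ``n_repeats`` independent permutations).  A feature used in no
    split has importance exactly 0.
    """
    X, y = _require_training_data(forest)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    importances = np.zeros(forest.n_features)
    usable = 0
    for rec in forest.trees:
        oob = rec.oob_indices
        if oob.size == 0:
            continue
        usable += 1
        X_oob = X[oob]
        y_oob = y[oob]
        base_err = float(np.mean(rec.tree.predict(X_oob) != y_oob))
        used = rec.tree.used_features()
        for i in range(forest.n_features):
            if i not in used:
                continue  # permuting an unused feature cannot change output
            delta = 0.0
            for _ in range(n_repeats):
                Xp = X_oob.copy()
                Xp[:, i] = Xp[rng.permutation(oob.size), i]
                delta += float(np.mean(rec.tree.predict(Xp) != y_oob)) - base_err
            importances[i] += delta / n_repeats
    if usable == 0:
        raise ValueError("no tree has out-of-bag samples")
    return importances / usable


def forest_to_json(forest: WeightedForest) -> str:
    """Serialize trees, weights and params to a documented JSON structure."""
    payload = {
        "params": {
            "n_trees": forest.params.n_trees,
            "max_depth": forest.params.max_depth,
            "min_leaf": forest.params.min_leaf,
            "mtry": forest.params.mtry,
            "seed": forest.params.seed,
        },
        "n_features": forest.n_features,
        "trees": [
            {
                "children_left": rec.tree.children_left.tolist(),
                "children_right": rec.tree.children_right.tolist(),
                "feature": rec.tree.feature.tolist(),
                "threshold": rec.tree.threshold.tolist(),
                "leaf_class": rec.tree.leaf_class.tolist(),
                "oob_accuracy": rec.oob_accuracy,
                "weight": rec.weight,
            }
            for rec in forest.trees
        ],
    }
    return json.dumps(payload)


def forest_from_json(text: str) -> WeightedForest:
    """Rebuild a prediction-ready forest (training data not restored)."""
    payload = json.loads(text)
    params = ForestParams(**payload["params"])
    n_features = payload["n_features"]
    records = []
    for td in payload["trees"]:
        tree = ArrayTree(
            children_left=np.asarray(td["children_left"], dtype=np.intp),
            children_right=np.asarray(td["children_right"], dtype=np.intp),
            feature=np.asarray(td["feature"], dtype=np.intp),
            threshold=np.asarray(td["threshold"], dtype=float),
            leaf_class=np.asarray(td["leaf_class"], dtype=int),
            n_features=n_features,
        )
        records.append(TreeRecord(tree=tree,
                                  bootstrap_indices=np.empty(0, dtype=np.intp),
                                  oob_indices=np.empty(0, dtype=np.intp),
                                  oob_accuracy=td["oob_accuracy"],
                                  weight=td["weight"]))
    return WeightedForest(trees=tuple(records), params=params,
                          n_features=n_features, X=None, y=None)
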