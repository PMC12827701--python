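"""End-to-end hybrid pipeline: features -> selection -> forest + LR -> fusion.

``fit_hybrid`` runs the full training pipeline on a labeled cohort
table: fit the min-max normalizer, synthesize per-individual signals,
extract multi-domain wavelet features, assemble the candidate pool
(raw normalized variables, derived features, or their union), score and
adaptive-threshold-select features, fit the OOB-weighted forest and the
batch-gradient-descent logistic regression on the selected columns, and
freeze every stage's state into a :class:`HybridModel`.

Prediction fuses the two component probabilities convexly::

    P_final(y=1|x) = g * P_RF(y=1|x) + (1 - g) * P_LR(y=1|x)

with fusion weight g in [0, 1] (default 0.5; ``tune_g`` grid-searches a
validation set).  Evaluation covers accuracy / precision / recall / F1,
the ROC curve and AUC, stratified k-fold cross-validation with the
whole pipeline refit inside each training fold, and percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import feature_scoring, logistic_bgd, weighted_forest
from .feature_scoring import ASTConfig
from .signal_builder import (DEFAULT_SIGNAL_LENGTH, NormalizerState,
                             build_signals, default_variable_order,
                             fit_normalizer)
from .synthetic_cohort import LABEL_COLUMN
from .wavelet_features import WaveletSpec, feature_matrix, feature_names
from .weighted_forest import ForestParams

__all__ = [
    "PipelineConfig",
    "HybridModel",
    "EvalReport",
    "fit_hybrid",
    "predict_components",
    "predict_proba",
    "predict",
    "tune_g",
    "evaluate",
    "cross_validate",
    "bootstrap_ci",
    "model_to_json",
    "model_from_json",
]

POOLS = ("raw", "derived", "union")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the training pipeline needs, in one frozen record."""

    variable_order: tuple[str, ...] | None = None
    signal_length: int = DEFAULT_SIGNAL_LENGTH
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    pool: str = "union"
    n_bins: int = 10
    ast: ASTConfig = field(default_factory=ASTConfig)
    forest: ForestParams = field(default_factory=ForestParams)
    learning_rate: float = logistic_bgd.DEFAULT_LEARNING_RATE
    iterations: int = logistic_bgd.DEFAULT_ITERATIONS
    g: float = 0.5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.pool not in POOLS:
            raise ValueError(f"pool must be one of {POOLS}")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("fusion weight g must lie in [0, 1]")


@dataclass(frozen=True)
class HybridModel:
    """Frozen pipeline state; the predict path uses nothing else."""

    config: PipelineConfig
    normalizer: NormalizerState
    candidate_names: tuple[str, ...]
    scores: pd.DataFrame
    mask: np.ndarray
    forest: weighted_forest.WeightedForest
    lr: logistic_bgd.LRModel
    lr_trace: logistic_bgd.TrainTrace | None
    g: float

    @property
    def selected_names(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.candidate_names)[self.mask])


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    tp: int
    fp: int
    fn: int
    tn: int
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    threshold: float
    ci: dict | None = None

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("accuracy", "precision", "recall", "f1", "auc", "tp", "fp", "fn", "tn")}
        if self.ci is not None:
            d["ci"] = self.ci
        return d


def _candidate_matrix(table: pd.DataFrame, normalizer: NormalizerState,
                      config: PipelineConfig):
    """Assemble (names, matrix) for the configured candidate pool."""
    names: list[str] = []
    blocks: list[np.ndarray] = []
    raw = normalizer.transform(
        table.loc[:, list(normalizer.variable_order)].to_numpy(float)
    )
    if config.pool in ("raw", "union"):
        names.extend(normalizer.variable_order)
        blocks.append(raw)
    if config.pool in ("derived", "union"):
        signals = build_signals(table, normalizer, config.signal_length)
        names.extend(feature_names(config.wavelet))
        blocks.append(feature_matrix(signals, config.wavelet))
    return tuple(names), np.column_stack(blocks)


def fit_hybrid(table: pd.DataFrame, config: PipelineConfig = PipelineConfig()) -> HybridModel:
    """Train the full pipeline on a labeled cohort table."""
    if LABEL_COLUMN not in table.columns:
        raise ValueError("table lacks a label column")
    y = table[LABEL_COLUMN].to_numpy(int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    order = (config.variable_order if config.variable_order is not None
             else default_variable_order(table))
    normalizer = fit_normalizer(table, order)
    names, X = _candidate_matrix(table, normalizer, config)
    scores = feature_scoring.score_features(X, y, feature_names=names,
                                            n_bins=config.n_bins)
    mask = feature_scoring.ast_select(scores, config.ast)
    X_sel = X[:, mask]
    forest_params = replace(config.forest, seed=config.seed)
    forest = weighted_forest.fit_forest(X_sel, y, forest_params)
    sel_names = tuple(np.asarray(names)[mask])
    lr, trace = logistic_bgd.fit_bgd(X_sel, y, learning_rate=config.learning_rate,
                                     iterations=config.iterations,
                                     feature_names=sel_names, seed=config.seed)
    return HybridModel(config=config, normalizer=normalizer,
                       candidate_names=names, scores=scores, mask=mask,
                       forest=forest, lr=lr, lr_trace=trace, g=config.g)


def predict_components(model: HybridModel, table: pd.DataFrame):
    """Component probabilities ``(P_RF, P_LR)`` of the positive class."""
    _, X = _candidate_matrix(table, model.normalizer, model.config)
    X_sel = X[:, model.mask]
    p_rf = weighted_forest.predict_proba(model.forest, X_sel)[:, 1]
    p_lr = logistic_bgd.predict_proba(model.lr, X_sel)
    return p_rf, p_lr


def predict_proba(model: HybridModel, table: pd.DataFrame, g: float | None = None) -> np.ndarray:
    """Fused positive-class probability, g*P_RF + (1-g)*P_LR."""
    g = model.g if g is None else g
    if not 0.0 <= g <= 1.0:
        raise ValueError("fusion weight g must lie in [0, 1]")
    p_rf, p_lr = predict_components(model, table)
    return g * p_rf + (1.0 - g) * p_lr


def predict(model: HybridModel, table: pd.DataFrame) -> np.ndarray:
    return (predict_proba(model, table) >= model.config.threshold).astype(int)


def tune_g(model: HybridModel, validation: pd.DataFrame,
           grid=None) -> float:
    """Grid-search g maximizing validation AUC; ties prefer g near 0.5."""
    if LABEL_COLUMN not in validation.columns:
        raise ValueError("validation table lacks a label column")
    grid = np.round(np.arange(0.0, 1.0001, 0.05), 2) if grid is None else np.asarray(grid, float)
    y = validation[LABEL_COLUMN].to_numpy(int)
    p_rf, p_lr = predict_components(model, validation)
    best = None
    for g in grid:
        score = _fast_auc(g * p_rf + (1.0 - g) * p_lr, y)
        key = (-score, abs(g - 0.5), g)
        if best is None or key < best[0]:
            best = (key, float(g))
    return best[1]


def _fast_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC with the half-credit tie correction."""
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


_METRICS = {
    "auc": lambda p, y, thr: _fast_auc(p, y),
    "accuracy": lambda p, y, thr: float(np.mean((p >= thr).astype(int) == y)),
    "recall": lambda p, y, thr: _confusion_metric(p, y, thr, "recall"),
    "precision": lambda p, y, thr: _confusion_metric(p, y, thr, "precision"),
    "f1": lambda p, y, thr: _confusion_metric(p, y, thr, "f1"),
}


def _confusion_metric(p, y, thr, which):
    pred = (np.asarray(p) >= thr).astype(int)
    y = np.asarray(y)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if which == "precision":
        return precision
    if which == "recall":
        return recall
    return (2 * precision * recall / (precision + recall)
            if precision + recall else 0.0)


def evaluate(probabilities, labels, threshold: float = 0.5) -> EvalReport:
    """Confusion metrics at the threshold plus the full ROC curve / AUC."""
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if p.size != y.size:
        raise ValueError("probabilities and labels lengths differ")
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined for single-class labels")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    accuracy = (tp + tn) / y.size
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    return EvalReport(accuracy=float(accuracy), precision=float(precision),
                      recall=float(recall), f1=float(f1),
                      auc=float(_trapezoid_auc(fpr, tpr)),
                      tp=tp, fp=fp, fn=fn, tn=tn,
                      roc_fpr=fpr, roc_tpr=tpr, threshold=threshold)


def cross_validate(table: pd.DataFrame, config: PipelineConfig = PipelineConfig(),
                   k: int = 10, seed: int = 0):
    """Stratified k-fold CV refitting the entire pipeline per fold.

    Returns ``(fold_reports, summary)`` where summary maps metric name
    to ``(mean, sd)`` over folds.  No statistic of any test fold leaks
    into its training fold.
    """
    y = table[LABEL_COLUMN].to_numpy(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError("a class is too rare to stratify into k folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[EvalReport] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(y.size), y)):
        fold_config = replace(config, seed=config.seed + fold)
        model = fit_hybrid(table.iloc[train_idx].reset_index(drop=True), fold_config)
        probs = predict_proba(model, table.iloc[test_idx].reset_index(drop=True))
        reports.append(evaluate(probs, y[test_idx], threshold=config.threshold))
    summary = {
        name: (float(np.mean([getattr(r, name) for r in reports])),
               float(np.std([getattr(r, name) for r in reports])))
        for name in ("accuracy", "precision", "recall", "f1", "auc")
    }
    return reports, summary


def bootstrap_ci(probabilities, labels, metric="auc", B: int = 1000,
                 level: float = 0.95, threshold: float = 0.5,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for a metric of (probability, label) pairs.

    Resamples with one class only are redrawn (at most 100 retries per
    resample).  ``metric`` is a name from accuracy/precision/recall/f1/auc
    or a callable ``metric(probabilities, labels)``.
    """
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if p.size != y.size:
        raise ValueError("probabilities and labels lengths differ")
    if p.size < 30:
        raise ValueError("bootstrap needs at least 30 pairs")
    if callable(metric):
        fn = lambda pp, yy: float(metric(pp, yy))
    else:
        base = _METRICS[metric]
        fn = lambda pp, yy: float(base(pp, yy, threshold))
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    for b in range(B):
        for attempt in range(100):
            idx = rng.integers(0, p.size, size=p.size)
            if np.unique(y[idx]).size == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class resample in 100 tries")
        values[b] = fn(p[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lower), float(upper)


def model_to_json(model: HybridModel) -> str:
    """Serialize the frozen pipeline state to JSON (predict-ready)."""
    cfg = model.config
    payload = {
        "config": {
            "variable_order": list(cfg.variable_order) if cfg.variable_order else None,
            "signal_length": cfg.signal_length,
            "wavelet": {"family": cfg.wavelet.family, "levels": cfg.wavelet.levels},
            "pool": cfg.pool,
            "n_bins": cfg.n_bins,
            "ast": {"alpha": cfg.ast.alpha, "beta": cfg.ast.beta},
            "forest": {"n_trees": cfg.forest.n_trees, "max_depth": cfg.forest.max_depth,
                       "min_leaf": cfg.forest.min_leaf, "mtry": cfg.forest.mtry,
                       "seed": cfg.forest.seed},
            "learning_rate": cfg.learning_rate,
            "iterations": cfg.iterations,
            "g": cfg.g,
            "threshold": cfg.threshold,
            "seed": cfg.seed,
        },
        "normalizer": {
            "variable_order": list(model.normalizer.variable_order),
            "mins": list(model.normalizer.mins),
            "maxs": list(model.normalizer.maxs),
        },
        "candidate_names": list(model.candidate_names),
        "scores": model.scores.to_dict(orient="list"),
        "mask": model.mask.astype(int).tolist(),
        "forest": json.loads(weighted_forest.forest_to_json(model.forest)),
        "lr": logistic_bgd.model_to_dict(model.lr),
        "g": model.g,
    }
    return json.dumps(payload)


def model_from_json(text: str) -> HybridModel:
    payload = json.loads(text)
    c = payload["config"]
    config = PipelineConfig(
        variable_order=tuple(c["variable_order"]) if c["variable_order"] else None,
        signal_length=c["signal_length"],
        wavelet=WaveletSpec(**c["wavelet"]),
        pool=c["pool"],
        n_bins=c["n_bins"],
        ast=ASTConfig(**c["ast"]),
        forest=ForestParams(**c["forest"]),
        learning_rate=c["learning_rate"],
        iterations=c["iterations"],
        g=c["g"],
        threshold=c["threshold"],
        seed=c["seed"],
    )
    norm = payload["normalizer"]
    normalizer = NormalizerState(variable_order=tuple(norm["variable_order"]),
                                 mins=tuple(norm["mins"]), maxs=tuple(norm["maxs"]))
    return HybridModel(
        config=config,
        normalizer=normalizer,
        candidate_names=tuple(payload["candidate_names"]),
        scores=pd.DataFrame(payload["scores"]),
        mask=np.asarray(payload["mask"], dtype=bool),
        forest=weighted_forest.forest_from_json(json.dumps(payload["forest"])),
        lr=logistic_bgd.model_from_dict(payload["lr"]),
        lr_trace=None,
        g=float(payload["g"]),
    )
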