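"""Filter feature selection: gain ratio, mutual information, adaptive threshold.

Each candidate feature is discretized (equal-frequency bins for
continuous features, passthrough for low-cardinality integer
features), scored against the binary target by the Quinlan information
gain ratio and by mutual information, and retained only when both
scores strictly exceed coefficient-scaled maxima:

    retain F  iff  IGR(F) > alpha * IGR_max  and  MI(F) > beta * MI_max

with alpha, beta in (0, 1].  Raising either coefficient can only shrink
the retained set.  If the strict conjunction empties the mask (e.g.
alpha = beta = 1), the feature with maximal IGR + MI is retained as a
documented fallback.  All entropies use natural logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ASTConfig",
    "discretize",
    "entropy",
    "info_gain_ratio",
    "mutual_information",
    "score_features",
    "ast_select",
]


@dataclass(frozen=True)
class ASTConfig:
    """Adaptive-selection-threshold coefficients, each in (0, 1]."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


def discretize(values, n_bins: int = 10):
    """Bin a feature column; returns (integer codes, bin edges or None).

    Low-cardinality integer-valued features (<= n_bins distinct values)
    pass through as categories (edges None).  Otherwise equal-frequency
    bins are formed on the unique quantiles, so ties collapse bins and
    a constant vector yields a single bin.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    uniques = np.unique(x)
    integral = np.allclose(x, np.round(x))
    if integral and uniques.size <= n_bins:
        codes = np.searchsorted(uniques, x)
        return codes.astype(np.intp), None
    edges = np.unique(np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1)))
    interior = edges[1:-1]
    codes = np.searchsorted(interior, x, side="left")
    return codes.astype(np.intp), edges


def entropy(labels) -> float:
    """Shannon entropy (nats) of empirical category frequencies."""
    codes = np.asarray(labels).ravel()
    if codes.size == 0:
        raise ValueError("entropy of an empty sample is undefined")
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _joint_counts(f, y) -> np.ndarray:
    f = np.asarray(f).ravel()
    y = np.asarray(y).ravel()
    if f.size != y.size:
        raise ValueError("feature and target lengths differ")
    _, fi = np.unique(f, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((fi.max() + 1, yi.max() + 1))
    np.add.at(joint, (fi, yi), 1.0)
    return joint


def info_gain_ratio(feature_bins, target) -> float:
    """Information gain of the feature about the target, over H(F).

    A constant feature (H(F) = 0) scores 0 by convention.
    """
    joint = _joint_counts(feature_bins, target)
    n = joint.sum()
    pf = joint.sum(axis=1) / n
    h_f = float(-(pf[pf > 0] * np.log(pf[pf > 0])).sum())
    if h_f == 0.0:
        return 0.0
    pr = joint.sum(axis=0) / n
    h_r = float(-(pr[pr > 0] * np.log(pr[pr > 0])).sum())
    # H(R|F) = sum_f p(f) H(R | F=f)
    h_r_given_f = 0.0
    for row, w in zip(joint, pf):
        if w == 0.0:
            continue
        cond = row / row.sum()
        cond = cond[cond > 0]
        h_r_given_f += w * float(-(cond * np.log(cond)).sum())
    return (h_r - h_r_given_f) / h_f


def mutual_information(feature_bins, target) -> float:
    """MI(F;R) = sum g(f,r) ln[g(f,r) / (g(f) g(r))], in nats.

    Zero-count cells contribute 0; the result is non-negative up to
    rounding.
    """
    joint = _joint_counts(feature_bins, target)
    n = joint.sum()
    p = joint / n
    pf = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (pf @ pr)), 0.0)
    return max(float(terms.sum()), 0.0)


def score_features(X, y, feature_names=None, n_bins: int = 10) -> pd.DataFrame:
    """Score every column of X; returns a table (feature, igr, mi, h_f)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if feature_names is None else list(feature_names)
        matrix = X.to_numpy(float)
    else:
        matrix = np.asarray(X, dtype=float)
        names = (list(feature_names) if feature_names is not None
                 else [f"f{i}" for i in range(matrix.shape[1])])
    y = np.asarray(y).ravel()
    rows = []
    for j, name in enumerate(names):
        codes, _ = discretize(matrix[:, j], n_bins=n_bins)
        rows.append({
            "feature": name,
            "igr": info_gain_ratio(codes, y),
            "mi": mutual_information(codes, y),
            "h_f": entropy(codes),
        })
    return pd.DataFrame(rows)


def ast_select(scores: pd.DataFrame, cfg: ASTConfig = ASTConfig()) -> np.ndarray:
    """Adaptive-threshold retention mask over a score table.

    Strict conjunction of the two scaled-maximum conditions; if no
    feature survives, the single feature maximizing IGR + MI is
    retained (documented fallback).
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    igr = scores["igr"].to_numpy(float)
    mi = scores["mi"].to_numpy(float)
    mask = (igr > cfg.alpha * igr.max()) & (mi > cfg.beta * mi.max())
    if not mask.any():
        mask = np.zeros(len(scores), dtype=bool)
        mask[int(np.argmax(igr + mi))] = True
    return mask
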