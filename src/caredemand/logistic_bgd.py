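"""Logistic regression fit by full-batch gradient descent on cross-entropy.

The model is P(y=1|x) = sigmoid(b0 + sum_u b_u x_u).  Training
standardizes features internally (z-score on training statistics),
starts from theta = 0, and takes full-batch steps

    theta <- theta - a * (1/m) X'(h - y)

recording the loss trace.  Defaults: learning rate a = 0.01 and 500
iterations.  A mini-batch mode exists behind ``batch_size=`` for
comparison, but full batch is the default path: with standardized
features and this step size the convex cross-entropy decreases
monotonically.  Coefficients are mapped back to the original feature
scale before being reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["LRModel", "TrainTrace", "predict_proba", "gradient", "loss", "fit_bgd",
           "model_to_dict", "model_from_dict"]

DEFAULT_LEARNING_RATE = 0.01
DEFAULT_ITERATIONS = 500


@dataclass(frozen=True)
class LRModel:
    intercept: float
    coef: np.ndarray
    feature_names: tuple[str, ...]
    train_mean: np.ndarray
    train_sd: np.ndarray


@dataclass(frozen=True)
class TrainTrace:
    """Loss at initialization and after each of the ``iterations`` steps."""

    losses: np.ndarray
    learning_rate: float
    iterations: int


def predict_proba(model: LRModel, X) -> np.ndarray:
    """P(y=1|x); numerically stable for arbitrarily large linear terms."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.coef.size:
        raise ValueError(f"expected {model.coef.size} features, got {X.shape[1]}")
    return expit(model.intercept + X @ model.coef)


def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def loss(theta, X, y) -> float:
    """Mean cross-entropy at theta (theta[0] is the intercept)."""
    Xb = _with_intercept(np.asarray(X, dtype=float))
    z = Xb @ np.asarray(theta, dtype=float)
    # log(1 + e^z) - y z, computed without overflow; NaN inputs propagate
    # silently so the caller can report the offending iteration
    with np.errstate(invalid="ignore"):
        return float(np.mean(np.logaddexp(0.0, z) - np.asarray(y, float) * z))


def gradient(theta, X, y) -> np.ndarray:
    """(1/m) X'(h - y), with the intercept as a constant pseudo-feature."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty sample")
    Xb = _with_intercept(X)
    h = expit(Xb @ np.asarray(theta, dtype=float))
    return Xb.T @ (h - y) / y.size


def fit_bgd(X, y, learning_rate: float = DEFAULT_LEARNING_RATE,
            iterations: int = DEFAULT_ITERATIONS, feature_names=None,
            batch_size: int | None = None, seed: int = 0):
    """Gradient-descent fit; returns ``(LRModel, TrainTrace)``.

    ``batch_size=None`` (default) is full batch; an integer enables the
    mini-batch variant with shuffled epochs.  Raises on a non-finite
    loss, naming the iteration.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    names = (tuple(feature_names) if feature_names is not None
             else tuple(f"x{u}" for u in range(X.shape[1])))
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    Xs = (X - mean) / sd_safe

    theta = np.zeros(X.shape[1] + 1)
    losses = np.empty(iterations + 1)
    rng = np.random.default_rng(seed)
    n = y.size
    for it in range(iterations):
        losses[it] = loss(theta, Xs, y)
        if not np.isfinite(losses[it]):
            raise FloatingPointError(f"non-finite loss at iteration {it}")
        if batch_size is None:
            theta = theta - learning_rate * gradient(theta, Xs, y)
        else:
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                theta = theta - learning_rate * gradient(theta, Xs[idx], y[idx])
    losses[iterations] = loss(theta, Xs, y)
    if not np.isfinite(losses[iterations]):
        raise FloatingPointError(f"non-finite loss at iteration {iterations}")

    coef = theta[1:] / sd_safe
    intercept = float(theta[0] - np.sum(theta[1:] * mean / sd_safe))
    model = LRModel(intercept=intercept, coef=coef, feature_names=names,
                    train_mean=mean, train_sd=sd)
    trace = TrainTrace(losses=losses, learning_rate=learning_rate,
                       iterations=iterations)
    return model, trace


def model_to_dict(model: LRModel) -> dict:
    return {
        "intercept": model.intercept,
        "coef": model.coef.tolist(),
        "feature_names": list(model.feature_names),
        "train_mean": model.train_mean.tolist(),
        "train_sd": model.train_sd.tolist(),
    }


def model_from_dict(d: dict) -> LRModel:
    return LRModel(
        intercept=float(d["intercept"]),
        coef=np.asarray(d["coef"], dtype=float),
        feature_names=tuple(d["feature_names"]),
        train_mean=np.asarray(d["train_mean"], dtype=float),
        train_sd=np.asarray(d["train_sd"], dtype=float),
    )
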