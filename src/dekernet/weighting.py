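"""Weight-focused edge scoring: per-target random-forest importances (the
GENIE3 scheme) and an absolute-Pearson-correlation baseline.

Both produce a dense directed weight matrix W with W[i, j] = weight of the
edge j -> i (feature j as a predictor of feature i). These weights rank
edges; they do not by themselves define a network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .dataset import Dataset


@dataclass(frozen=True)
class DirectedWeightMatrix:
    """Dense nonnegative directed edge weights; W[i, j] scores j -> i.

    The diagonal is zero (no self-edges)."""

    W: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        n = len(self.feature_names)
        if W.shape != (n, n):
            raise ValueError(f"weight matrix shape {W.shape} != ({n}, {n})")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diagonal(W) != 0):
            raise ValueError("self-edge weights must be zero")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))


def genie3_weights(
    data: Dataset,
    n_trees: int = 1000,
    candidate_predictors: str = "all",
    seed: int = 0,
) -> DirectedWeightMatrix:
    """GENIE3-style edge weights: for each target feature, regress it on all
    other features with a random forest and take each predictor's total
    variance-reduction importance.

    Importances are normalized per target (each row sums to 1) so weights
    are comparable across targets; a constant target has no variance to
    explain and gets an all-zero row. Per-target forests draw their
    randomness from independent streams spawned from ``seed``.
    """
    if candidate_predictors != "all":
        raise ValueError("only candidate_predictors='all' is supported")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    n = data.n_features
    W = np.zeros((n, n))
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    for target in range(n):
        X_pred, y, _ = data.response_view(target)
        if np.ptp(y) == 0.0:
            continue  # constant target: nothing to reduce
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=1.0,  # K = 'all'
            random_state=np.random.default_rng(child_seeds[target]).integers(2**31),
            n_jobs=1,
        )
        rf.fit(X_pred, y)
        importances = rf.feature_importances_  # impurity reduction, sums to 1
        total = importances.sum()
        if total > 0:
            importances = importances / total
        others = [j for j in range(n) if j != target]
        W[target, others] = importances
    return DirectedWeightMatrix(W=W, feature_names=data.feature_names)


def correlation_weights(data: Dataset) -> DirectedWeightMatrix:
    """Absolute Pearson correlation between every feature pair; symmetric,
    in [0, 1]. Constant columns get zero weight everywhere."""
    X = data.X
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    C = np.abs(Z.T @ Z) / X.shape[0]
    C = np.clip(C, 0.0, 1.0)
    np.fill_diagonal(C, 0.0)
    return DirectedWeightMatrix(W=C, feature_names=data.feature_names)
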