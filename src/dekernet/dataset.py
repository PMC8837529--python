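"""Expression dataset container.

A dataset is a samples-by-features matrix of normalized expression values
with unique feature names. All inference entry points consume this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Dataset:
    """Samples x features expression matrix with named columns.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Expression values. Must be finite.
    feature_names : tuple of str
        Unique, non-empty identifiers, one per column.
    """

    X: np.ndarray
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"expression matrix must be 2-D, got ndim={X.ndim}")
        if X.shape[0] < 3:
            raise ValueError(f"need at least 3 samples, got {X.shape[0]}")
        if X.shape[1] < 2:
            raise ValueError(f"need at least 2 features, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("expression matrix contains non-finite values")
        names = tuple(self.feature_names) or tuple(
            f"G{j + 1}" for j in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise ValueError(
                f"{len(names)} feature names for {X.shape[1]} columns"
            )
        if any(not n for n in names):
            raise ValueError("feature names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]

    def response_view(self, j: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Split the matrix into (predictors, response) with feature j as response.

        Returns the predictor matrix (all columns but j), the response vector
        (column j) and the predictor names, preserving column order.
        """
        mask = np.ones(self.n_features, dtype=bool)
        mask[j] = False
        names = [n for i, n in enumerate(self.feature_names) if i != j]
        return self.X[:, mask], self.X[:, j], names
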