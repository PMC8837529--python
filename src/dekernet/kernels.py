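"""Weighted squared-exponential kernel and leave-one-out kernel regression.

The kernel operates on feature vectors scaled elementwise by nonnegative
weights w: k(a, b) = exp(-d / (2 * lengthscale**2)) where d is the Euclidean
norm of w * (a - b). By default the norm enters the exponent unsquared; the
conventional squared form is available through ``KernelConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

DistanceForm = Literal["unsquared_l2", "squared_l2"]


@dataclass(frozen=True)
class KernelConfig:
    """Kernel hyperparameters.

    lengthscale : characteristic lengthscale l_f > 0; controls the size of
        the neighborhood that dominates each prediction.
    distance_in_exponent : whether the L2 norm in the exponent is used as-is
        ("unsquared_l2", default) or squared ("squared_l2").
    """

    lengthscale: float = 1.0
    distance_in_exponent: DistanceForm = "unsquared_l2"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lengthscale) and self.lengthscale > 0):
            raise ValueError(f"lengthscale must be positive, got {self.lengthscale}")
        if self.distance_in_exponent not in ("unsquared_l2", "squared_l2"):
            raise ValueError(
                f"unknown distance form {self.distance_in_exponent!r}"
            )


def _check_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def weighted_kernel(
    x_a: np.ndarray, x_b: np.ndarray, w: np.ndarray, cfg: KernelConfig
) -> float:
    """Kernel similarity of two samples under feature weights w.

    Returns a value in (0, 1]; equals 1 exactly when the weighted difference
    vector is zero. Symmetric in its two sample arguments.
    """
    x_a = _check_vector(x_a, "x_a")
    x_b = _check_vector(x_b, "x_b")
    w = _check_vector(w, "w")
    if not (x_a.shape == x_b.shape == w.shape):
        raise ValueError(
            f"dimension mismatch: {x_a.shape}, {x_b.shape}, {w.shape}"
        )
    diff = w * (x_a - x_b)
    d = float(np.linalg.norm(diff))
    if cfg.distance_in_exponent == "squared_l2":
        d = d * d
    return float(np.exp(-d / (2.0 * cfg.lengthscale**2)))


def loocv_predict(
    X: np.ndarray,
    y: np.ndarray,
    held_out_index: int,
    w: np.ndarray,
    cfg: KernelConfig,
) -> float:
    """Predict one response from all others by kernel-weighted averaging.

    The held-out sample is excluded from its own prediction; the result is a
    convex combination of the remaining responses and therefore lies within
    their range.
    """
    X = np.asarray(X, dtype=float)
    y = _check_vector(y, "y")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    if X.shape[0] < 2:
        raise ValueError("leave-one-out prediction requires at least 2 samples")
    if not 0 <= held_out_index < X.shape[0]:
        raise IndexError(f"held_out_index {held_out_index} out of range")
    others = np.ones(X.shape[0], dtype=bool)
    others[held_out_index] = False
    weights = np.array(
        [weighted_kernel(X[held_out_index], X[i], w, cfg) for i in np.nonzero(others)[0]]
    )
    return float(np.sum(weights * y[others]) / np.sum(weights))
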