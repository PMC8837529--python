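"""Small seeded synthetic instances used by the test suite and examples.

These are first-class generators (not stored data): each returns a freshly
drawn instance that is bitwise reproducible at a given seed.
"""

from __future__ import annotations

import numpy as np


def planted_regression(
    seed: int = 0,
    n_samples: int = 60,
    n_noise_features: int = 5,
    noise_sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """One informative predictor among independent noise features.

    The response is the first column plus Gaussian noise of standard
    deviation ``noise_sd``; the remaining columns are independent standard
    normal draws. A correct selector should pick exactly column 0.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, 1 + n_noise_features))
    y = X[:, 0] + noise_sd * rng.normal(size=n_samples)
    return X, y


def pure_noise_regression(
    seed: int = 0, n_samples: int = 60, n_features: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Response independent of every predictor; a correct selector should
    declare the result uninformative."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, n_features))
    y = rng.normal(size=n_samples)
    return X, y


def separating_feature() -> tuple[np.ndarray, np.ndarray]:
    """Four samples where the single feature perfectly separates the
    response classes at threshold 1: every margin is positive."""
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    return X, y
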