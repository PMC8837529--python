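"""Decomposed kernel regression: threshold partitions, margins, and the
penalized margin objective.

The regression problem y ~ X is decomposed into a family of binary
classification problems, one per response threshold t_k: samples fall below
or at/above the threshold. For each sample i and threshold k the margin
m(i, k) is the kernel-normalized mean L1 distance (in weighted feature
space) from sample i to the *incorrect* subset minus the distance to the
*correct* subset, with sample i excluded from both neighbor sets. A positive
margin means the weighted features place the sample closer to its own class.

Feature selection minimizes sum_{i,k} loss(m(i,k)) + lambda * sum_j w_j over
w >= 0, where the default loss is the logistic margin loss
log(1 + exp(-m)) — smooth and margin-maximizing — and the L1 penalty drives
uninformative feature weights to exactly zero.

Distance conventions: the kernel exponent uses the (by default unsquared)
L2 norm of the weighted difference, while the distance terms inside the
margin use the L1 norm. The asymmetry is deliberate — L1 margin distances
keep the derivative simple and piecewise linear in w.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit

from .kernels import KernelConfig

MarginLoss = Literal["logistic", "linear"]

#: kernel mass below this is numerically indistinguishable from an empty
#: neighbor set (after row rescaling the nearest neighbor has mass 1)
_DEN_FLOOR = 1e-250


@dataclass(frozen=True)
class ThresholdPartition:
    """Samples split at a response threshold: below vs at-or-above."""

    threshold: float
    below: np.ndarray  # indices with y_i < threshold
    at_or_above: np.ndarray  # indices with y_i >= threshold

    @property
    def valid(self) -> bool:
        """A partition is usable only if both sides are non-empty."""
        return self.below.size > 0 and self.at_or_above.size > 0


def partition_by_threshold(y: np.ndarray, threshold: float) -> ThresholdPartition:
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    idx = np.arange(y.shape[0])
    below = idx[y < threshold]
    return ThresholdPartition(
        threshold=float(threshold), below=below, at_or_above=idx[y >= threshold]
    )


def valid_thresholds(y: np.ndarray, stride: int = 1) -> np.ndarray:
    """Candidate thresholds: every distinct observed response value that
    splits the samples into two non-empty subsets.

    Every response value is a candidate; duplicates are collapsed and the
    minimum is dropped (its below-set is empty). ``stride`` keeps every
    stride-th threshold (a documented speed/accuracy trade-off: fewer
    thresholds cost some resolution of the response distribution).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    uniq = np.unique(y)
    ts = uniq[1:]  # t = min(y) leaves the below-set empty
    return ts[::stride]


@dataclass(frozen=True)
class MarginTable:
    """Margins m(i, k) for every sample i and valid threshold t_k.

    labels holds the true class y^c_{i,k}: -1 when y_i < t_k, +1 otherwise.
    decision holds the unsigned decision value (distance-to-below minus
    distance-to-above); m = labels * decision.
    """

    m: np.ndarray  # (n_samples, n_thresholds)
    labels: np.ndarray  # (n_samples, n_thresholds), values in {-1, +1}
    thresholds: np.ndarray  # (n_thresholds,)

    @property
    def n_observations(self) -> int:
        return int(self.m.size)

    @property
    def decision(self) -> np.ndarray:
        return self.m * self.labels


class MarginProblem:
    """Precomputed quantities for repeated margin/objective evaluation on a
    fixed (X, y, thresholds) instance.

    Caches the pairwise per-feature absolute and squared differences
    (n_samples^2 x n_features each) so that every objective and gradient
    evaluation reduces to dense matrix products. Used by the optimizer; the
    module-level functions wrap one-shot use.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        cfg: KernelConfig,
        thresholds: np.ndarray | None = None,
        loss: MarginLoss = "logistic",
    ) -> None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in X or y")
        if thresholds is None:
            thresholds = valid_thresholds(y)
        else:
            thresholds = np.asarray(thresholds, dtype=float).ravel()
            keep = [partition_by_threshold(y, t).valid for t in thresholds]
            thresholds = thresholds[np.asarray(keep, dtype=bool)]
        if thresholds.size == 0:
            raise ValueError(
                "degenerate response: no threshold splits the samples into "
                "two non-empty subsets"
            )
        if loss not in ("logistic", "linear"):
            raise ValueError(f"unknown margin loss {loss!r}")

        self.X = X
        self.y = y
        self.cfg = cfg
        self.loss: MarginLoss = loss
        self.thresholds = thresholds
        self.n_samples, self.n_features = X.shape

        diff = X[:, None, :] - X[None, :, :]  # (N, N, P)
        self._absdiff = np.abs(diff)
        self._sqdiff = diff * diff
        # below mask B[i, k] = 1 iff y_i < t_k; labels = -1 below, +1 at/above
        B = (y[:, None] < thresholds[None, :]).astype(float)
        self._B = B
        self._labels = np.where(B > 0, -1.0, 1.0)

    # -- internal pieces -------------------------------------------------

    def _pairwise(self, w: np.ndarray):
        """Kernel matrix F (zero diagonal = self-exclusion), L1 distances D1,
        and the weighted L2 distances d2 at weights w.

        F is rescaled row-wise so each sample's nearest neighbor has kernel
        value 1: margins and the objective only ever use F through ratios
        F_ij / sum_j F_ij within a row, so the rescaling is exact while
        preventing underflow at short lengthscales.
        """
        w = np.asarray(w, dtype=float).ravel()
        if w.shape[0] != self.n_features:
            raise ValueError(
                f"weight vector length {w.shape[0]} != {self.n_features} features"
            )
        D1 = self._absdiff @ w
        s2 = self._sqdiff @ (w * w)
        d2 = np.sqrt(np.maximum(s2, 0.0))
        l2 = 2.0 * self.cfg.lengthscale**2
        E = s2 if self.cfg.distance_in_exponent == "squared_l2" else d2
        E = E / l2
        E_offdiag = E + np.diag(np.full(self.n_samples, np.inf))
        row_min = np.min(E_offdiag, axis=1, keepdims=True)
        F = np.exp(-(E - row_min))
        np.fill_diagonal(F, 0.0)
        return F, D1, d2

    def _subset_terms(self, F: np.ndarray, D1: np.ndarray):
        """Normalized mean weighted L1 distance of each sample to each
        subset (below / at-or-above), per threshold.

        Where the self-excluded subset is empty the distance is taken as
        zero (the sample simply has no neighbors on that side).
        """
        FD = F * D1
        out = []
        for M in (self._B, 1.0 - self._B):
            den = F @ M
            num = FD @ M
            ok = den > _DEN_FLOOR
            T = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
            out.append((T, den))
        return out  # [(T_below, den_below), (T_above, den_above)]

    # -- public evaluations ----------------------------------------------

    def margins(self, w: np.ndarray) -> MarginTable:
        F, D1, _ = self._pairwise(w)
        (Tb, _), (Ta, _) = self._subset_terms(F, D1)
        m = self._labels * (Tb - Ta)
        return MarginTable(
            m=m, labels=self._labels.astype(int), thresholds=self.thresholds
        )

    def _loss_and_dloss(self, m: np.ndarray):
        if self.loss == "logistic":
            # log(1 + exp(-m)) evaluated stably; derivative -sigmoid(-m)
            return np.logaddexp(0.0, -m), -expit(-m)
        return m, np.ones_like(m)

    def objective(self, w: np.ndarray, lambda_: float = 0.0) -> float:
        if lambda_ < 0:
            raise ValueError("lambda_ must be nonnegative")
        m = self.margins(w).m
        loss, _ = self._loss_and_dloss(m)
        return float(np.sum(loss) + lambda_ * np.sum(w))

    def objective_and_gradient(
        self, w: np.ndarray, lambda_: float = 0.0
    ) -> tuple[float, np.ndarray]:
        """Objective value and its analytic gradient with respect to w.

        Differentiable wherever all pairwise weighted L2 distances are
        positive; at exact ties (identical samples, or w = 0) the
        kernel-derivative term is assigned its limiting value of zero.
        """
        if lambda_ < 0:
            raise ValueError("lambda_ must be nonnegative")
        w = np.asarray(w, dtype=float).ravel()
        F, D1, d2 = self._pairwise(w)
        (Tb, den_b), (Ta, den_a) = self._subset_terms(F, D1)
        m = self._labels * (Tb - Ta)
        loss, dloss = self._loss_and_dloss(m)
        value = float(np.sum(loss) + lambda_ * np.sum(w))

        c = dloss * self._labels  # d obj / d (Tb - Ta), per (i, k)
        R = np.zeros_like(F)
        Q = np.zeros_like(F)
        for sign, M, T, den in (
            (1.0, self._B, Tb, den_b),
            (-1.0, 1.0 - self._B, Ta, den_a),
        ):
            ok = den > _DEN_FLOOR
            CS = np.where(ok, sign * c / np.where(ok, den, 1.0), 0.0)
            R += CS @ M.T
            Q += (CS * T) @ M.T

        H = F * (R * D1 - Q)
        FR = F * R
        # d exponent / d w_p: -w_p * sq_ijp / (2 l^2 d2_ij) for the unsquared
        # form, -w_p * sq_ijp / l^2 for the squared form.
        if self.cfg.distance_in_exponent == "squared_l2":
            scaled_H = H / self.cfg.lengthscale**2
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                scaled_H = np.where(d2 > 0, H / np.where(d2 > 0, d2, 1.0), 0.0)
            scaled_H = scaled_H / (2.0 * self.cfg.lengthscale**2)
        kernel_term = -w * np.einsum("ij,ijp->p", scaled_H, self._sqdiff)
        distance_term = np.einsum("ij,ijp->p", FR, self._absdiff)
        grad = kernel_term + distance_term + lambda_
        return value, grad


# -- one-shot functional wrappers ----------------------------------------


def compute_margins(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    cfg: KernelConfig,
    thresholds: np.ndarray | None = None,
) -> MarginTable:
    """Margin table at feature weights w (see module docstring)."""
    return MarginProblem(X, y, cfg, thresholds=thresholds).margins(w)


def objective(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    cfg: KernelConfig,
    lambda_: float = 0.0,
    thresholds: np.ndarray | None = None,
    loss: MarginLoss = "logistic",
) -> float:
    """Penalized margin objective sum loss(m) + lambda * sum w."""
    return MarginProblem(X, y, cfg, thresholds=thresholds, loss=loss).objective(
        w, lambda_
    )


def objective_gradient(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    cfg: KernelConfig,
    lambda_: float = 0.0,
    thresholds: np.ndarray | None = None,
    loss: MarginLoss = "logistic",
) -> np.ndarray:
    """Analytic gradient of :func:`objective` with respect to w."""
    problem = MarginProblem(X, y, cfg, thresholds=thresholds, loss=loss)
    return problem.objective_and_gradient(w, lambda_)[1]
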