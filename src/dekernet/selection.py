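"""Feature selection by penalized margin optimization with BIC model
selection.

For a fixed lengthscale and penalty, nonnegative feature weights are found
by minimizing the penalized margin objective (see :mod:`dekernet.margins`).
Hyperparameters are then chosen by Bayesian Information Criterion: the
margins of each fitted model are converted to probabilities of correct
classification with Platt scaling, giving a log-likelihood, and the BIC
penalizes the number of selected features (plus the two calibration
parameters). A model is kept only if its BIC beats a predictor-free null
model that predicts every threshold's class base rate — otherwise the
selection is declared uninformative and contributes nothing downstream.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from scipy.special import expit

from .kernels import KernelConfig
from .margins import MarginLoss, MarginProblem, MarginTable, valid_thresholds

#: weights below this after optimization are numerical dust, not selections
ZERO_TOLERANCE = 1e-6


@dataclass(frozen=True)
class Hyperparameters:
    """Kernel lengthscale l_f and L1 penalty weight lambda."""

    lengthscale: float
    penalty: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lengthscale) and self.lengthscale > 0):
            raise ValueError("lengthscale must be positive")
        if not (np.isfinite(self.penalty) and self.penalty >= 0):
            raise ValueError("penalty must be nonnegative")


@dataclass(frozen=True)
class SolverConfig:
    """Settings for the weight optimizer.

    method: "lbfgsb" (default; bound-constrained quasi-Newton) or
        "projected_gradient" (gradient step, clamp at zero, backtracking
        line search).
    tol: convergence tolerance on the relative objective change.
    max_iter: iteration cap; hitting it flags (not raises) non-convergence.
    """

    method: Literal["lbfgsb", "projected_gradient"] = "lbfgsb"
    tol: float = 1e-8
    max_iter: int = 500


@dataclass(frozen=True)
class OptimizedWeights:
    w: np.ndarray
    converged: bool
    n_iter: int
    objective: float
    message: str = ""

    @property
    def selected(self) -> np.ndarray:
        """Indices of features with weight above the zero tolerance."""
        return np.nonzero(self.w > ZERO_TOLERANCE)[0]


@dataclass(frozen=True)
class PlattCalibration:
    """Sigmoid map from margins to probability of correct classification:
    P(correct | m) = 1 / (1 + exp(slope * m + intercept)), slope <= 0."""

    slope: float
    intercept: float

    def probability(self, margins: np.ndarray) -> np.ndarray:
        return expit(-(self.slope * np.asarray(margins, dtype=float) + self.intercept))


@dataclass(frozen=True)
class SelectionModel:
    hyperparameters: Hyperparameters
    weights: np.ndarray
    selected: tuple[int, ...]
    calibration: PlattCalibration
    log_likelihood: float
    degrees_of_freedom: float
    bic: float
    converged: bool = True


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of feature selection for one response.

    ``informative`` is True only when the best model's BIC beats the null
    BIC and at least one feature is selected; non-informative responses
    contribute no edges to an inferred network.
    """

    response_feature: str
    best_model: SelectionModel | None
    null_bic: float
    informative: bool
    grid_trace: tuple[tuple[Hyperparameters, float, int], ...] = ()
    status: str = "ok"

    @property
    def selected(self) -> tuple[int, ...]:
        if self.best_model is None or not self.informative:
            return ()
        return self.best_model.selected


# -- weight optimization ---------------------------------------------------


def _projected_gradient(
    problem: MarginProblem, lambda_: float, w0: np.ndarray, cfg: SolverConfig
) -> OptimizedWeights:
    w = np.maximum(w0, 0.0)
    f, g = problem.objective_and_gradient(w, lambda_)
    step = 1.0
    for it in range(1, cfg.max_iter + 1):
        # backtracking on the projected step (Armijo on the actual decrease)
        accepted = False
        for _ in range(40):
            w_new = np.maximum(w - step * g, 0.0)
            f_new = problem.objective(w_new, lambda_)
            if f_new <= f - 1e-4 * np.sum(g * (w - w_new)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return OptimizedWeights(w, True, it, f, "line search stalled at a stationary point")
        rel = abs(f - f_new) / max(1.0, abs(f))
        w, f = w_new, f_new
        _, g = problem.objective_and_gradient(w, lambda_)
        step = min(step * 2.0, 1e3)
        if rel < cfg.tol:
            return OptimizedWeights(w, True, it, f)
    return OptimizedWeights(w, False, cfg.max_iter, f, "max iterations reached")


def optimize_weights(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters,
    init: np.ndarray | None = None,
    solver_config: SolverConfig | None = None,
    *,
    problem: MarginProblem | None = None,
    loss: MarginLoss = "logistic",
) -> OptimizedWeights:
    """Minimize the penalized margin objective over w >= 0.

    Deterministic: identical inputs and solver settings give bitwise
    identical weights. Non-convergence within the iteration cap is reported
    on the result, never raised.
    """
    cfg = solver_config or SolverConfig()
    if problem is None:
        problem = MarginProblem(
            X, y, KernelConfig(lengthscale=hp.lengthscale), loss=loss
        )
    n_p = problem.n_features
    w0 = np.ones(n_p) if init is None else np.asarray(init, dtype=float).ravel()
    if w0.shape[0] != n_p:
        raise ValueError("init length does not match the number of predictors")
    if np.any(w0 < 0):
        raise ValueError("init weights must be nonnegative")

    if cfg.method == "projected_gradient":
        return _projected_gradient(problem, hp.penalty, w0, cfg)

    res = minimize(
        lambda w: problem.objective_and_gradient(w, hp.penalty),
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * n_p,
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-7},
    )
    w = np.maximum(res.x, 0.0)
    w[w <= ZERO_TOLERANCE * 1e-3] = 0.0  # strip solver dust far below tolerance
    return OptimizedWeights(
        w=w,
        converged=bool(res.success) or res.status == 0,
        n_iter=int(res.nit),
        objective=float(res.fun),
        message=str(res.message),
    )


def lambda_max(problem: MarginProblem, eps: float = 1e-3) -> float:
    """Data-derived penalty bound: the smallest lambda at which the
    objective gradient at (near-)zero weights is nonnegative in every
    coordinate, so the all-zero solution is stationary.

    Evaluated at w = eps * ones because the kernel term of the gradient is
    directional at exactly zero.
    """
    w = np.full(problem.n_features, eps)
    _, g = problem.objective_and_gradient(w, 0.0)
    return float(max(np.max(-g), 0.0))


# -- Platt scaling and BIC -------------------------------------------------


def platt_calibrate(scores: np.ndarray, labels: np.ndarray) -> PlattCalibration:
    """Fit a sigmoid mapping classifier scores to P(positive class).

    ``scores`` are the unsigned decision values (here: the margin before it
    is signed by the true class — distance-to-below minus distance-to-above,
    where positive predicts the at-or-above class) and ``labels`` the true
    binary outcomes. Uses Platt's regularized targets: positive observations
    get target (N+ + 1)/(N+ + 2), negatives 1/(N- + 2), which keeps the fit
    finite under perfect separation. The slope is constrained nonpositive so
    a larger score never lowers the fitted probability.
    """
    m = np.asarray(scores, dtype=float).ravel()
    if m.size == 0:
        raise ValueError("no observations to calibrate")
    correct = np.asarray(labels).ravel() > 0
    if correct.shape != m.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(np.sum(correct))
    n_neg = m.size - n_pos
    t = np.where(correct, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    if np.ptp(m) == 0.0:
        # constant covariate: intercept-only fit at the smoothed base rate
        base = float(np.mean(t))
        return PlattCalibration(slope=0.0, intercept=float(np.log((1 - base) / base)))

    def nll_and_grad(params: np.ndarray):
        a, b = params
        z = a * m + b
        p = expit(-z)
        eps = 1e-12
        nll = -np.sum(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps))
        d_z = t - p  # d nll / d z
        return nll, np.array([np.sum(d_z * m), np.sum(d_z)])

    b0 = float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    res = minimize(
        nll_and_grad,
        np.array([-1.0, b0]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, 0.0), (None, None)],
    )
    return PlattCalibration(slope=float(res.x[0]), intercept=float(res.x[1]))


def platt_log_likelihood(
    scores: np.ndarray, labels: np.ndarray, calibration: PlattCalibration
) -> float:
    """Log-likelihood of the observed classes under the calibrated sigmoid:
    each sample lands on the correct side of its threshold with the fitted
    probability."""
    m = np.asarray(scores, dtype=float).ravel()
    pos = np.asarray(labels).ravel() > 0
    p = np.clip(calibration.probability(m), 1e-12, 1 - 1e-12)
    return float(np.sum(np.where(pos, np.log(p), np.log(1 - p))))


def model_bic(
    margins: MarginTable,
    calibration: PlattCalibration,
    n_selected: int,
    n_obs: int | None = None,
) -> float:
    """BIC = -2 * (log L / n_thresholds) + df * log(n_obs) with
    df = n_selected + 2 (the two Platt parameters count toward model
    complexity).

    The likelihood is that of each sample's true threshold class given its
    decision value and the calibration. The per-threshold classification
    problems are correlated views of a single regression on n_samples
    independent samples, so the deviance is averaged over thresholds and the
    effective observation count n_obs defaults to the number of samples —
    otherwise the likelihood term would swamp the complexity penalty by a
    factor of the threshold count.
    """
    if margins.m.size == 0:
        raise ValueError("empty margin set")
    if n_obs is None:
        n_obs = margins.m.shape[0]
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    ll = platt_log_likelihood(margins.decision, margins.labels, calibration)
    df = n_selected + 2
    return float(-2.0 * ll / margins.m.shape[1] + df * np.log(n_obs))


def null_bic(y: np.ndarray, thresholds: np.ndarray | None = None) -> float:
    """BIC of the predictor-free model: at each valid threshold every
    sample's probability of landing on its own side is that side's
    Laplace-smoothed base rate; zero degrees of freedom. The deviance is
    averaged over thresholds, matching :func:`model_bic`."""
    y = np.asarray(y, dtype=float).ravel()
    if thresholds is None:
        thresholds = valid_thresholds(y)
    thresholds = np.asarray(thresholds, dtype=float).ravel()
    n = y.size
    ll = 0.0
    n_valid = 0
    for t in thresholds:
        n_below = int(np.sum(y < t))
        n_above = n - n_below
        if n_below == 0 or n_above == 0:
            continue
        p_below = (n_below + 1.0) / (n + 2.0)
        p_above = (n_above + 1.0) / (n + 2.0)
        ll += n_below * np.log(p_below) + n_above * np.log(p_above)
        n_valid += 1
    if n_valid == 0:
        raise ValueError("no valid thresholds")
    return float(-2.0 * ll / n_valid)


# -- grid search -----------------------------------------------------------


@dataclass(frozen=True)
class GridConfig:
    """Hyperparameter grid specification.

    Lengthscales are log-spaced over [lengthscale_span] x (median pairwise
    L2 distance of the standardized predictors); penalties are log-spaced
    over [penalty_span] x lambda_max (computed per lengthscale, since the
    penalty bound depends on the kernel).
    """

    n_lengthscales: int = 8
    n_penalties: int = 8
    lengthscale_span: tuple[float, float] = (0.1, 10.0)
    penalty_span: tuple[float, float] = (0.01, 1.0)
    threshold_stride: int = 1


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance columns; constant columns map to all zeros
    (they carry no information and must never be selected)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = X - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def median_pairwise_distance(X: np.ndarray) -> float:
    d = pdist(np.asarray(X, dtype=float))
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


def lengthscale_grid(X_std: np.ndarray, grid: GridConfig) -> np.ndarray:
    med = median_pairwise_distance(X_std)
    lo, hi = grid.lengthscale_span
    return np.geomspace(lo * med, hi * med, grid.n_lengthscales)


def penalty_grid(lam_max: float, grid: GridConfig) -> np.ndarray:
    lam_max = max(lam_max, 1e-6)
    lo, hi = grid.penalty_span
    return np.geomspace(lo * lam_max, hi * lam_max, grid.n_penalties)


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    lengthscale_grid_values: Sequence[float] | None = None,
    penalty_grid_values: Sequence[float] | None = None,
    solver_config: SolverConfig | None = None,
    *,
    grid: GridConfig | None = None,
    response_feature: str = "y",
    loss: MarginLoss = "logistic",
) -> SelectionResult:
    """Grid-search hyperparameters, optimize weights at each point, and keep
    the minimum-BIC model if it beats the predictor-free null.

    Predictor columns are standardized internally so one lengthscale grid
    applies to all features. Ties in BIC prefer fewer selected features,
    then larger penalty, then smaller lengthscale. Fully deterministic.
    """
    grid = grid or GridConfig()
    solver_config = solver_config or SolverConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    X_std = standardize_columns(X)
    thresholds = valid_thresholds(y, stride=grid.threshold_stride)

    if lengthscale_grid_values is None:
        lengthscale_grid_values = lengthscale_grid(X_std, grid)
    ls_values = np.asarray(lengthscale_grid_values, dtype=float)

    null = null_bic(y, thresholds)
    trace: list[tuple[Hyperparameters, float, int]] = []
    candidates: list[tuple[tuple, SelectionModel]] = []
    any_converged = False

    base_problem: MarginProblem | None = None
    for lf in ls_values:
        cfg = KernelConfig(lengthscale=float(lf))
        if base_problem is None:
            base_problem = MarginProblem(X_std, y, cfg, thresholds=thresholds, loss=loss)
            problem = base_problem
        else:
            # the cached pairwise tensors are lengthscale-independent
            problem = copy.copy(base_problem)
            problem.cfg = cfg
        if penalty_grid_values is None:
            lam_values = penalty_grid(lambda_max(problem), grid)
        else:
            lam_values = np.asarray(penalty_grid_values, dtype=float)
        for lam in lam_values:
            hp = Hyperparameters(lengthscale=float(lf), penalty=float(lam))
            opt = optimize_weights(
                X_std, y, hp, solver_config=solver_config, problem=problem, loss=loss
            )
            any_converged = any_converged or opt.converged
            mt = problem.margins(opt.w)
            calib = platt_calibrate(mt.decision.ravel(), mt.labels.ravel())
            n_sel = opt.selected.size
            bic = model_bic(mt, calib, n_sel)
            trace.append((hp, bic, n_sel))
            if not opt.converged:
                continue
            model = SelectionModel(
                hyperparameters=hp,
                weights=opt.w,
                selected=tuple(int(j) for j in opt.selected),
                calibration=calib,
                log_likelihood=platt_log_likelihood(mt.decision, mt.labels, calib),
                degrees_of_freedom=float(n_sel + 2),
                bic=bic,
                converged=opt.converged,
            )
            key = (bic, n_sel, -hp.penalty, hp.lengthscale)
            candidates.append((key, model))

    if not candidates:
        return SelectionResult(
            response_feature=response_feature,
            best_model=None,
            null_bic=null,
            informative=False,
            grid_trace=tuple(trace),
            status="no grid point converged",
        )
    candidates.sort(key=lambda item: item[0])
    best = candidates[0][1]
    informative = bool(best.bic < null and len(best.selected) > 0)
    return SelectionResult(
        response_feature=response_feature,
        best_model=best,
        null_bic=null,
        informative=informative,
        grid_trace=tuple(trace),
        status="ok" if any_converged else "no grid point converged",
    )
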