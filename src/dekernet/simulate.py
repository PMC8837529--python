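"""Multifactorial steady-state data simulator.

Emulates the statistical structure of DREAM4-style multifactorial
benchmarks: every sample is an independent draw from a *common* ground-truth
regulatory network, but carries its own hidden perturbations — a random
handful of nodes receive random basal shifts — plus measurement noise. This
is the clinical-patient analogue (every patient differs in unknown ways) and
the hardest regime for network inference.

Dynamics are linear-Gaussian at steady state: with signed interaction
strengths A (A[i, j] = effect of node j on node i, spectral radius < 1) and
per-sample perturbation vector b, expression solves x = A x + b, i.e.
x = (I - A)^-1 b, observed with additive Gaussian noise. An optional
saturating (tanh) propagation nonlinearity is available for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import canonical_pair
from .dataset import Dataset
from .evaluation import GoldStandard


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Directed signed interaction network with real-valued strengths.

    strength[i, j] != 0 encodes an edge j -> i; the matrix has zero diagonal
    and spectral radius below 1 so the linear steady state exists and is
    unique.
    """

    strength: np.ndarray
    feature_names: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.strength, dtype=float)
        n = len(self.feature_names)
        if A.shape != (n, n):
            raise ValueError(f"strength matrix shape {A.shape} != ({n}, {n})")
        if not np.all(np.isfinite(A)):
            raise ValueError("strengths must be finite")
        if np.any(np.diagonal(A) != 0):
            raise ValueError("self-loops are not allowed")
        rho = spectral_radius(A)
        if rho >= 1.0:
            raise ValueError(f"unstable network: spectral radius {rho:.3f} >= 1")
        object.__setattr__(self, "strength", A)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_nodes(self) -> int:
        return len(self.feature_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.strength))

    def directed_edges(self) -> set[tuple[str, str]]:
        """(source, target) pairs with nonzero strength."""
        rows, cols = np.nonzero(self.strength)
        names = self.feature_names
        return {(names[j], names[i]) for i, j in zip(rows, cols)}

    def gold_standard(self) -> GoldStandard:
        """Undirected collapse of the directed edge set."""
        pairs = {canonical_pair(a, b) for a, b in self.directed_edges()}
        return GoldStandard(
            true_edges=frozenset(pairs), feature_names=self.feature_names
        )


def spectral_radius(A: np.ndarray) -> float:
    eig = np.linalg.eigvals(np.asarray(A, dtype=float))
    return float(np.max(np.abs(eig))) if eig.size else 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    perturbation_count: number of nodes perturbed per sample, or an
        inclusive (low, high) range sampled uniformly. Default (3, 10)
        mirrors the multiple-hidden-perturbations regime of the DREAM4
        multifactorial benchmarks.
    perturbation_scale: standard deviation of each perturbed node's basal
        shift.
    noise_sd: measurement noise standard deviation; None sets it to 5% of
        the noiseless signal's standard deviation.
    """

    n_samples: int = 100
    perturbation_count: int | tuple[int, int] = (3, 10)
    perturbation_scale: float = 1.0
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        pc = self.perturbation_count
        lo, hi = (pc, pc) if isinstance(pc, int) else pc
        if lo < 0 or hi < lo:
            raise ValueError(f"bad perturbation_count {pc!r}")
        if self.perturbation_scale <= 0:
            raise ValueError("perturbation_scale must be positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def sample_network(
    n_nodes: int, mean_degree: float = 2.0, seed: int = 0
) -> GroundTruthNetwork:
    """Draw a random ground-truth network with preferential-attachment-
    flavored in-degrees, random signs, and strengths rescaled so the
    spectral radius is at most 0.9.

    Acts as a stand-in for curated benchmark topologies when none is
    supplied; reproducible per seed.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if mean_degree < 1:
        raise ValueError("mean_degree must be >= 1")
    n_edges = int(round(n_nodes * mean_degree))
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError("mean_degree infeasible for this node count")
    rng = np.random.default_rng(seed)
    names = tuple(f"G{i + 1}" for i in range(n_nodes))
    A = np.zeros((n_nodes, n_nodes))
    in_deg = np.ones(n_nodes)  # +1 smoothing keeps every node reachable
    edges: set[tuple[int, int]] = set()
    while len(edges) < n_edges:
        target = int(rng.choice(n_nodes, p=in_deg / in_deg.sum()))
        source = int(rng.integers(n_nodes))
        if source == target or (source, target) in edges:
            continue
        edges.add((source, target))
        in_deg[target] += 1.0
        sign = rng.choice([-1.0, 1.0])
        A[target, source] = sign * rng.uniform(0.5, 1.0)
    rho = spectral_radius(A)
    if rho > 0.9:
        A *= 0.9 / rho
    return GroundTruthNetwork(strength=A, feature_names=names, seed=seed)


def steady_state(
    net: GroundTruthNetwork, b: np.ndarray, nonlinearity: str | None = None
) -> np.ndarray:
    """Solve x = A x + b (unique for spectral radius < 1); with
    nonlinearity='tanh', iterate x <- tanh(A x) + b to a fixed point."""
    A = net.strength
    if nonlinearity is None:
        return np.linalg.solve(np.eye(net.n_nodes) - A, b)
    if nonlinearity != "tanh":
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    x = b.copy()
    for _ in range(10_000):
        x_new = np.tanh(A @ x) + b
        if np.max(np.abs(x_new - x)) < 1e-12:
            return x_new
        x = x_new
    raise RuntimeError("fixed-point iteration did not converge")


def simulate_multifactorial(
    net: GroundTruthNetwork,
    cfg: SimulationConfig,
    nonlinearity: str | None = None,
) -> tuple[Dataset, GoldStandard]:
    """Simulate a multifactorial dataset from a ground-truth network.

    Each sample perturbs a random subset of nodes with Gaussian basal
    shifts, solves the steady state, and adds measurement noise. Returns the
    samples x nodes matrix and the undirected gold standard of the
    generating network. Reproducible per cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = net.n_nodes
    pc = cfg.perturbation_count
    lo, hi = (pc, pc) if isinstance(pc, int) else pc
    hi = min(hi, n)
    X = np.zeros((cfg.n_samples, n))
    for s in range(cfg.n_samples):
        k = int(rng.integers(lo, hi + 1))
        b = np.zeros(n)
        if k > 0:
            nodes = rng.choice(n, size=k, replace=False)
            b[nodes] = cfg.perturbation_scale * rng.normal(size=k)
        X[s] = steady_state(net, b, nonlinearity=nonlinearity)
    noise_sd = cfg.noise_sd
    if noise_sd is None:
        signal_sd = float(X.std())
        noise_sd = 0.05 * (signal_sd if signal_sd > 0 else 1.0)
    if noise_sd > 0:
        X = X + noise_sd * rng.normal(size=X.shape)
    return (
        Dataset(X=X, feature_names=net.feature_names),
        net.gold_standard(),
    )
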