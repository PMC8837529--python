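"""Network assembly: iterate feature selection over every feature as the
response, union the selected predictor->response edges, and weight the
resulting sparse undirected network with GENIE3 edge weights.

The division of labor is deliberate: the margin-based selector decides
*which* edges exist (its optimized weights are not comparable across
responses, so they are discarded), while the random-forest importances —
which are comparable — supply the edge weights and ranking. Candidate edges
that the random forest ranks very low (at or below a configurable quantile
of all pairwise collapsed weights) are excluded, exploiting the
complementarity of the two methods in both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .selection import GridConfig, SelectionResult, SolverConfig, select_features
from .weighting import DirectedWeightMatrix, genie3_weights

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateEdgeSet:
    """Directed (predictor, response) pairs found by iterated feature
    selection, with the per-response selection results for diagnostics."""

    edges: frozenset[tuple[str, str]]
    feature_names: tuple[str, ...]
    results: tuple[SelectionResult, ...] = ()

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-pair {a!r} in candidate edges")

    def undirected_pairs(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.edges}


@dataclass(frozen=True)
class InferredNetwork:
    """Sparse undirected weighted network — the pipeline's product.

    Edges are (a, b, weight) with a < b lexicographically, no duplicates and
    no self-edges; weights are nonnegative and finite.
    """

    edges: tuple[tuple[str, str, float], ...]
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        seen = set()
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-edge {a!r}")
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"pair ({a!r}, {b!r}) not in canonical order")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a!r}, {b!r})")
            seen.add((a, b))
            if not (np.isfinite(w) and w >= 0):
                raise ValueError(f"bad weight {w!r} on ({a!r}, {b!r})")

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges}

    def ranked(self) -> list[tuple[str, str, float]]:
        """Edges by descending weight; ties broken by canonical pair order."""
        return sorted(self.edges, key=lambda e: (-e[2], e[0], e[1]))


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def deker_candidate_edges(
    data: Dataset,
    grid: GridConfig | None = None,
    solver_config: SolverConfig | None = None,
) -> CandidateEdgeSet:
    """Run feature selection once per feature (as response) and union the
    informative selections into directed candidate edges (selected feature
    -> response). Non-informative or failed responses contribute nothing.
    """
    edges: set[tuple[str, str]] = set()
    results: list[SelectionResult] = []
    for j, response in enumerate(data.feature_names):
        X_pred, y, pred_names = data.response_view(j)
        try:
            res = select_features(
                X_pred,
                y,
                grid=grid,
                solver_config=solver_config,
                response_feature=response,
            )
        except ValueError as exc:  # e.g. degenerate (constant) response
            logger.warning("response %s skipped: %s", response, exc)
            continue
        results.append(res)
        if res.informative and res.best_model is not None:
            n_margin = res.best_model.bic - res.null_bic
            logger.info(
                "response %s: %d predictors selected (BIC - null = %.1f)",
                response,
                len(res.selected),
                n_margin,
            )
            for idx in res.selected:
                edges.add((pred_names[idx], response))
        else:
            logger.info("response %s: uninformative (%s)", response, res.status)
    return CandidateEdgeSet(
        edges=frozenset(edges), feature_names=data.feature_names, results=tuple(results)
    )


def collapse_to_undirected(
    weights: DirectedWeightMatrix | dict[tuple[str, str], float],
) -> dict[tuple[str, str], float]:
    """Undirected weight of a pair = max over the two directions; a missing
    direction counts as zero. Keys are canonical (a < b) pairs."""
    out: dict[tuple[str, str], float] = {}
    if isinstance(weights, DirectedWeightMatrix):
        names = weights.feature_names
        n = len(names)
        for i in range(n):
            for j in range(i + 1, n):
                out[canonical_pair(names[i], names[j])] = float(
                    max(weights.W[i, j], weights.W[j, i])
                )
        return out
    for (a, b), w in weights.items():
        if a == b:
            raise ValueError(f"self-edge {a!r}")
        key = canonical_pair(a, b)
        out[key] = max(out.get(key, 0.0), float(w))
    return out


def rescale_weights(network: InferredNetwork) -> InferredNetwork:
    """Min-max rescale edge weights to [0, 1]; an all-equal (or single-edge)
    network maps every weight to 1. An empty network is returned unchanged."""
    if not network.edges:
        return network
    ws = np.array([w for _, _, w in network.edges])
    lo, hi = float(ws.min()), float(ws.max())
    if hi == lo:
        scaled = np.ones_like(ws)
    else:
        scaled = (ws - lo) / (hi - lo)
    edges = tuple(
        (a, b, float(s)) for (a, b, _), s in zip(network.edges, scaled)
    )
    return InferredNetwork(edges=edges, feature_names=network.feature_names)


def assemble_final_network(
    candidates: CandidateEdgeSet,
    genie3: DirectedWeightMatrix,
    exclusion_quantile: float = 0.1,
    rescale: bool = True,
) -> InferredNetwork:
    """Keep exactly the candidate pairs, weighted by their collapsed GENIE3
    weights, dropping any candidate whose weight falls at or below the
    ``exclusion_quantile`` of *all* collapsed pairwise weights.
    """
    if set(candidates.feature_names) != set(genie3.feature_names):
        raise ValueError("candidate edges and weight matrix feature sets differ")
    if not (0.0 <= exclusion_quantile < 1.0):
        raise ValueError("exclusion_quantile must be in [0, 1)")
    collapsed = collapse_to_undirected(genie3)
    pairs = sorted(candidates.undirected_pairs())
    if exclusion_quantile > 0.0 and collapsed:
        cutoff = float(np.quantile(np.array(list(collapsed.values())), exclusion_quantile))
        dropped = [p for p in pairs if collapsed[p] <= cutoff]
        if dropped:
            logger.info(
                "excluding %d candidate edge(s) at or below the %.0f%% weight "
                "quantile (cutoff %.4g): %s",
                len(dropped),
                100 * exclusion_quantile,
                cutoff,
                dropped,
            )
        pairs = [p for p in pairs if collapsed[p] > cutoff]
    net = InferredNetwork(
        edges=tuple((a, b, collapsed[(a, b)]) for a, b in pairs),
        feature_names=tuple(sorted(candidates.feature_names)),
    )
    return rescale_weights(net) if rescale else net


def infer_network(
    data: Dataset,
    grid: GridConfig | None = None,
    solver_config: SolverConfig | None = None,
    n_trees: int = 1000,
    exclusion_quantile: float = 0.1,
    seed: int = 0,
) -> tuple[InferredNetwork, CandidateEdgeSet, DirectedWeightMatrix]:
    """Full pipeline: iterated feature selection for the edge subset,
    random-forest importances for the weights, low-quantile exclusion, and
    min-max rescaling. Returns the network plus both intermediates."""
    candidates = deker_candidate_edges(data, grid=grid, solver_config=solver_config)
    weights = genie3_weights(data, n_trees=n_trees, seed=seed)
    network = assemble_final_network(
        candidates, weights, exclusion_quantile=exclusion_quantile
    )
    return network, candidates, weights
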