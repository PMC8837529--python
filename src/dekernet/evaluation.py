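"""Scoring inferred networks against a known gold standard.

Errors are split into two classes. An *indirect effect* error links two
features at distance exactly two in the true network (the endpoints share at
least one common neighbor, as in a -- b -- c inferred as a -- c); such
errors barely perturb network topology. All other false positives are more
serious. Precision-recall curves are therefore reported in two variants:
including all false positives, and excluding the indirect ones (recall is
unchanged; precision can only improve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import InferredNetwork, canonical_pair, collapse_to_undirected
from .weighting import DirectedWeightMatrix

Pair = tuple[str, str]


@dataclass(frozen=True)
class GoldStandard:
    """True undirected edge set of a benchmark network."""

    true_edges: frozenset[Pair]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = set(self.feature_names)
        for a, b in self.true_edges:
            if a == b:
                raise ValueError(f"self-pair {a!r} in gold standard")
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"gold pair ({a!r}, {b!r}) not canonical")
            if a not in names or b not in names:
                raise ValueError(f"gold pair ({a!r}, {b!r}) uses unknown features")

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.feature_names}
        for a, b in self.true_edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


@dataclass(frozen=True)
class EdgeClassification:
    """Inferred edges partitioned into true positives, indirect false
    positives (distance-2 in the gold graph) and other false positives,
    plus the false negatives. Conservation: TP + iFP + oFP = #inferred and
    TP + FN = #gold."""

    true_positives: tuple[Pair, ...]
    indirect_false_positives: tuple[Pair, ...]
    other_false_positives: tuple[Pair, ...]
    false_negatives: tuple[Pair, ...]

    @property
    def n_tp(self) -> int:
        return len(self.true_positives)

    @property
    def n_fp(self) -> int:
        return len(self.indirect_false_positives) + len(self.other_false_positives)

    @property
    def n_inferred(self) -> int:
        return self.n_tp + self.n_fp

    def precision(self, include_indirect: bool = True) -> float:
        """Fraction of inferred edges that are true. With
        include_indirect=False, indirect errors are removed from the
        denominator (the optimistic variant)."""
        denom = (
            self.n_inferred
            if include_indirect
            else self.n_tp + len(self.other_false_positives)
        )
        return self.n_tp / denom if denom else float("nan")

    def recall(self) -> float:
        n_true = self.n_tp + len(self.false_negatives)
        return self.n_tp / n_true if n_true else float("nan")


def classify_edges(
    inferred: InferredNetwork | set[Pair], gold: GoldStandard
) -> EdgeClassification:
    """Classify each inferred pair as TP, indirect FP (endpoints share a
    common neighbor in the gold graph) or other FP; list gold pairs missed
    as FN."""
    if isinstance(inferred, InferredNetwork):
        pairs = inferred.pairs
    else:
        pairs = {canonical_pair(a, b) for a, b in inferred}
    names = set(gold.feature_names)
    for a, b in pairs:
        if a not in names or b not in names:
            raise ValueError(f"inferred pair ({a!r}, {b!r}) uses unknown features")
    adj = gold.neighbors()
    tp, ifp, ofp = [], [], []
    for pair in sorted(pairs):
        a, b = pair
        if pair in gold.true_edges:
            tp.append(pair)
        elif adj[a] & adj[b]:
            ifp.append(pair)
        else:
            ofp.append(pair)
    fn = sorted(gold.true_edges - pairs)
    return EdgeClassification(
        true_positives=tuple(tp),
        indirect_false_positives=tuple(ifp),
        other_false_positives=tuple(ofp),
        false_negatives=tuple(fn),
    )


@dataclass(frozen=True)
class PRCurvePair:
    """Dual precision-recall curve: points ordered by descending retained
    edge count, from the full ranking down to a single edge. At every point
    precision_excluding >= precision_including and recall is shared."""

    points: tuple[tuple[int, float, float, float], ...]
    # each point: (kept_edges, recall, precision_incl, precision_excl)


def pr_curves(
    ranked_edges: list[tuple[str, str, float]] | InferredNetwork,
    gold: GoldStandard,
) -> PRCurvePair:
    """Precision-recall points generated by iteratively removing the
    lowest-ranked edge. Weight ties are broken by canonical pair order so
    curves are reproducible."""
    if not gold.true_edges:
        raise ValueError("empty gold standard")
    if isinstance(ranked_edges, InferredNetwork):
        ranking = ranked_edges.ranked()
    else:
        ranking = sorted(
            [(canonical_pair(a, b) + (float(w),)) for a, b, w in ranked_edges],
            key=lambda e: (-e[2], e[0], e[1]),
        )
    adj = gold.neighbors()
    n_true = len(gold.true_edges)
    # cumulative counts along the ranking
    tp = other = 0
    prefix_stats = []
    for a, b, _ in ranking:
        pair = (a, b)
        if pair in gold.true_edges:
            tp += 1
        elif not (adj.get(a, set()) & adj.get(b, set())):
            other += 1
        prefix_stats.append((tp, other))
    points = []
    for kept in range(len(ranking), 0, -1):
        tp_k, other_k = prefix_stats[kept - 1]
        recall = tp_k / n_true
        prec_incl = tp_k / kept
        denom_excl = tp_k + other_k
        prec_excl = tp_k / denom_excl if denom_excl else 1.0
        points.append((kept, recall, prec_incl, prec_excl))
    return PRCurvePair(points=tuple(points))


def net_positive_score(
    inferred: InferredNetwork | set[Pair], gold: GoldStandard
) -> int:
    """True positives minus all false positives — the net edge count
    heuristic for comparing whole networks. May be negative."""
    cls = classify_edges(inferred, gold)
    return cls.n_tp - cls.n_fp


def threshold_sweep(
    W: DirectedWeightMatrix,
    gold: GoldStandard,
    fractions: tuple[float, ...] = (0.02, 0.01, 0.008, 0.004),
) -> dict[float, tuple[EdgeClassification, int]]:
    """Literature-style thresholding of a dense weight matrix: collapse to
    undirected, rank, and keep the top fraction of all possible pairs
    (floored, minimum one edge); classify each resulting network.

    The default fractions are the commonly used top 2%, 1%, 0.8% and 0.4%.
    """
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fraction {f} outside (0, 1]")
    collapsed = collapse_to_undirected(W)
    ranking = sorted(collapsed.items(), key=lambda kv: (-kv[1], kv[0]))
    n_pairs = len(collapsed)
    out = {}
    for f in fractions:
        keep = max(1, int(np.floor(f * n_pairs)))
        pairs = {pair for pair, _ in ranking[:keep]}
        cls = classify_edges(pairs, gold)
        out[f] = (cls, cls.n_tp - cls.n_fp)
    return out
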