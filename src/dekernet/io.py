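"""Readers and writers for the DREAM-dialect plain-text formats.

Expression matrices are tab-separated with a feature-name header row and one
sample per subsequent row. Edge lists are three-column TSV
(source, target, value): gold standards use 0/1 values, predictions carry
real weights and are written in descending weight order.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import InferredNetwork, canonical_pair
from .dataset import Dataset
from .evaluation import GoldStandard, PRCurvePair


def read_expression_tsv(path: str | Path) -> Dataset:
    """Parse a tab-separated expression matrix (header row of feature
    names, numeric sample rows). Raises on ragged rows, non-numeric cells
    or duplicate names, naming the offending line."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        names = header.split("\t")
        if len(set(names)) != len(names):
            raise ValueError(f"{path}: duplicate feature names in header")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(names):
                raise ValueError(
                    f"{path}: line {lineno} has {len(cells)} fields, expected {len(names)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    X = np.asarray(rows, dtype=float)
    if X.size and not np.all(np.isfinite(X)):
        raise ValueError(f"{path}: non-finite expression values")
    return Dataset(X=X, feature_names=tuple(names))


def write_expression_tsv(data: Dataset, path: str | Path) -> None:
    df = pd.DataFrame(data.X, columns=list(data.feature_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edge_list(
    path: str | Path, feature_names: tuple[str, ...] | None = None
) -> GoldStandard:
    """Read a three-column edge list as a gold standard: rows with value 1
    are edges (collapsed to undirected), rows with value 0 are ignored."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields")
            a, b, val = cells
            try:
                v = float(val)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: bad value {val!r}") from None
            seen.update((a, b))
            if v != 0:
                if a == b:
                    raise ValueError(f"{path}: line {lineno}: self-edge {a!r}")
                pairs.add(canonical_pair(a, b))
    if feature_names is None:
        feature_names = tuple(sorted(seen))
    else:
        unknown = seen - set(feature_names)
        if unknown:
            raise ValueError(f"{path}: unknown features {sorted(unknown)}")
    return GoldStandard(true_edges=frozenset(pairs), feature_names=feature_names)


def read_weighted_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a prediction edge list: (source, target, real weight) rows."""
    out = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields")
            out.append((cells[0], cells[1], float(cells[2])))
    return out


def write_edge_list(
    network: InferredNetwork | GoldStandard, path: str | Path
) -> None:
    """Write an edge list: predictions in descending weight (ties in
    canonical pair order), gold standards with value 1 in pair order."""
    with Path(path).open("w") as fh:
        if isinstance(network, GoldStandard):
            for a, b in sorted(network.true_edges):
                fh.write(f"{a}\t{b}\t1\n")
        else:
            for a, b, w in network.ranked():
                fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_inferred_network(path: str | Path) -> InferredNetwork:
    edges = {}
    names: set[str] = set()
    for a, b, w in read_weighted_edges(path):
        pair = canonical_pair(a, b)
        edges[pair] = float(w)
        names.update(pair)
    return InferredNetwork(
        edges=tuple((a, b, w) for (a, b), w in sorted(edges.items())),
        feature_names=tuple(sorted(names)),
    )


def write_pr_table(curves: PRCurvePair, path: str | Path) -> None:
    df = pd.DataFrame(
        list(curves.points),
        columns=["kept_edges", "recall", "precision_incl", "precision_excl"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file's bytes, for run-log provenance."""
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
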