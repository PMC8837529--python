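"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops straight from the
definitions, deliberately sharing no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import math

import numpy as np


def naive_kernel(x_a, x_b, w, lengthscale, squared=False):
    d = math.sqrt(sum((wi * (ai - bi)) ** 2 for ai, bi, wi in zip(x_a, x_b, w)))
    if squared:
        d = d * d
    return math.exp(-d / (2.0 * lengthscale**2))


def naive_margins(X, y, w, lengthscale, thresholds, squared=False):
    """Margin m(i, k) per the defining double sums: kernel-normalized mean
    weighted L1 distance to the incorrect subset minus to the correct one,
    with sample i excluded from both neighbor sets and an empty
    self-excluded subset contributing distance zero."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    out = np.zeros((n, len(thresholds)))
    for k, t in enumerate(thresholds):
        below = [j for j in range(n) if y[j] < t]
        above = [j for j in range(n) if y[j] >= t]
        assert below and above, "invalid threshold passed to oracle"
        for i in range(n):
            dists = []
            for subset in (below, above):
                members = [j for j in subset if j != i]
                if not members:
                    dists.append(0.0)
                    continue
                ks = [naive_kernel(X[i], X[j], w, lengthscale, squared) for j in members]
                total = sum(ks)
                d = 0.0
                for kv, j in zip(ks, members):
                    l1 = sum(abs(wi * (ai - bi)) for ai, bi, wi in zip(X[i], X[j], w))
                    d += kv / total * l1
                dists.append(d)
            label = -1.0 if y[i] < t else 1.0
            out[i, k] = label * (dists[0] - dists[1])
    return out


def naive_objective(X, y, w, lengthscale, thresholds, lambda_, squared=False):
    m = naive_margins(X, y, w, lengthscale, thresholds, squared)
    loss = sum(math.log1p(math.exp(-v)) for v in m.ravel())
    return loss + lambda_ * float(np.sum(w))


def brute_force_classify(inferred_pairs, gold_pairs, nodes):
    """Edge classification by exhaustive common-neighbor enumeration."""
    gold = {tuple(sorted(p)) for p in gold_pairs}
    inferred = {tuple(sorted(p)) for p in inferred_pairs}
    tp, ifp, ofp = set(), set(), set()
    for a, b in inferred:
        if (a, b) in gold:
            tp.add((a, b))
            continue
        indirect = any(
            tuple(sorted((a, c))) in gold and tuple(sorted((b, c))) in gold
            for c in nodes
            if c not in (a, b)
        )
        (ifp if indirect else ofp).add((a, b))
    fn = gold - inferred
    return tp, ifp, ofp, fn


def fixed_point_steady_state(A, b, tol=1e-14, max_iter=200_000):
    """Long-run iteration x <- A x + b; converges for spectral radius < 1."""
    x = np.zeros(len(b))
    for _ in range(max_iter):
        x_new = A @ x + b
        if np.max(np.abs(x_new - x)) < tol:
            return x_new
        x = x_new
    raise RuntimeError("oracle iteration did not converge")
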