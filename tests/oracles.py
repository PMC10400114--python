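"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (triple loops, exhaustive
enumeration) and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by dynamic programming on a length matrix.

    ``lengths[i, j]`` is the direct edge length or inf; diagonal 0.
    """
    D = lengths.copy().astype(float)
    n = D.shape[0]
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def lengths_from_weights(W: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def global_efficiency_oracle(W: np.ndarray) -> float:
    n = W.shape[0]
    D = floyd_warshall(lengths_from_weights(W))
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def local_efficiency_oracle(W: np.ndarray) -> np.ndarray:
    """Per-node weighted local efficiency by explicit subgraph enumeration.

    For each node, builds the neighbour subgraph, runs Floyd-Warshall on
    cube-rooted edge lengths, and accumulates
    (w_uj * w_uh)^(1/3) / d'_jh over ordered neighbour pairs, normalized by
    k (k - 1).
    """
    n = W.shape[0]
    out = np.zeros(n)
    for u in range(n):
        V = [j for j in range(n) if W[u, j] > 0]
        k = len(V)
        if k < 2:
            continue
        sub = W[np.ix_(V, V)]
        D = floyd_warshall(lengths_from_weights(np.cbrt(sub)))
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(D[a, b]) and D[a, b] > 0:
                    acc += (W[u, V[a]] * W[u, V[b]]) ** (1.0 / 3.0) / D[a, b]
        out[u] = acc / (k * (k - 1))
    return out


def assortativity_oracle(W: np.ndarray) -> float | None:
    """Endpoint-strength Pearson correlation by explicit edge enumeration."""
    n = W.shape[0]
    s = W.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                xs.extend([s[i], s[j]])
                ys.extend([s[j], s[i]])
    if not xs:
        raise ValueError("edgeless graph")
    x = np.array(xs)
    y = np.array(ys)
    if np.var(x) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def random_weighted_graph(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric nonnegative matrix with zero diagonal, possibly disconnected."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.05, 2.0)
    return W
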