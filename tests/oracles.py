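"""Independent brute-force reference implementations used only by tests.

Deliberately naive: Floyd-Warshall distances, explicit triangle
enumeration, and literal definitions of the efficiency metrics, so they
share no code path with the package's vectorized implementations.
"""

import itertools

import numpy as np


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_degree(a: np.ndarray) -> np.ndarray:
    return np.array([sum(a[i, j] for j in range(a.shape[0])) for i in range(a.shape[0])])


def brute_clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for u, v in itertools.combinations(nbrs, 2) if a[u, v]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def brute_global_efficiency_per_node(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = floyd_warshall(a)
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]):
                s += 1.0 / d[i, j]
        out[i] = s / (n - 1)
    return out


def brute_subgraph_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(a)
    s = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                s += 1.0 / d[i, j]
    return s / (n * (n - 1))


def brute_local_efficiency(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) >= 2:
            sub = a[np.ix_(nbrs, nbrs)]
            out[i] = brute_subgraph_efficiency(sub)
    return out


def brute_path_length(a: np.ndarray) -> tuple[float, bool]:
    """Mean distance over reachable ordered pairs, and disconnected flag."""
    n = a.shape[0]
    d = floyd_warshall(a)
    vals, disconnected = [], False
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(d[i, j]):
                vals.append(d[i, j])
            else:
                disconnected = True
    return float(np.mean(vals)), disconnected


def brute_bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, literal definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj
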