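"""Topological metrics on binary undirected hemispheric networks.

Node level: degree centrality, clustering coefficient, nodal global
efficiency (mean inverse shortest-path length from a node to all
others) and nodal local efficiency (global efficiency of the subgraph
induced by a node's neighbours). Hemisphere level: mean clustering and
characteristic path length, normalized by the means of degree-preserving
rewired null networks (Maslov-Sneppen double edge swaps) to give the
normalized clustering coefficient gamma, normalized path length lambda,
and the small-world index sigma = gamma / lambda; sigma > 1 indicates
small-world organization.

Disconnected graphs are handled by convention rather than error: path
lengths average over reachable pairs only, unreachable pairs contribute
zero efficiency, and the output carries a ``disconnected`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

NODE_METRICS = (
    "degree_centrality",
    "nodal_global_efficiency",
    "clustering_coefficient",
    "nodal_local_efficiency",
)
HEMISPHERE_METRICS = ("gamma", "lambda", "sigma")


@dataclass
class NodeMetrics:
    """Per-node metric vectors for one binary network."""

    degree_centrality: np.ndarray
    clustering_coefficient: np.ndarray
    nodal_global_efficiency: np.ndarray
    nodal_local_efficiency: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in NODE_METRICS}


@dataclass
class HemisphereMetrics:
    """Small-world summary of one binary network."""

    mean_clustering: float
    path_length: float
    mean_clustering_rand: float
    path_length_rand: float
    gamma: float
    lambda_: float
    sigma: float
    disconnected: bool
    n_rewiring_exhausted: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"gamma": self.gamma, "lambda": self.lambda_, "sigma": self.sigma}


def _check_binary(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("adjacency must be binary (0/1)")
    return a


def _inverse_distances(a: np.ndarray) -> np.ndarray:
    """1/d_ij matrix with zeros on the diagonal and for unreachable pairs."""
    d = shortest_path(a, method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    return inv


def _global_efficiency(a: np.ndarray) -> float:
    """Mean inverse distance over ordered pairs; 0 for graphs of < 2 nodes."""
    n = a.shape[0]
    if n < 2:
        return 0.0
    return float(_inverse_distances(a).sum() / (n * (n - 1)))


def compute_node_metrics(adjacency: np.ndarray) -> NodeMetrics:
    """All four node-level metrics of one binary network."""
    a = _check_binary(adjacency)
    n = a.shape[0]
    k = a.sum(axis=1)

    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    clustering = np.divide(
        2.0 * triangles, denom, out=np.zeros(n), where=denom > 0
    )

    eglob = _inverse_distances(a).sum(axis=1) / (n - 1)

    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if len(nbrs) >= 2:
            eloc[i] = _global_efficiency(a[np.ix_(nbrs, nbrs)])

    return NodeMetrics(
        degree_centrality=k,
        clustering_coefficient=clustering,
        nodal_global_efficiency=eglob,
        nodal_local_efficiency=eloc,
    )


def compute_global_metrics(adjacency: np.ndarray) -> tuple[float, float, bool]:
    """(mean clustering, characteristic path length, disconnected flag).

    L averages shortest-path lengths over *reachable* ordered pairs.
    Raises on edgeless graphs, where L is undefined.
    """
    a = _check_binary(adjacency)
    if a.sum() == 0:
        raise ValueError("characteristic path length undefined for an edgeless graph")
    cbar = float(compute_node_metrics(a).clustering_coefficient.mean())
    d = shortest_path(a, method="D", unweighted=True)
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    disconnected = bool((~np.isfinite(d) & off).any())
    length = float(d[finite].mean())
    return cbar, length, disconnected


def rewire_null(
    adjacency: np.ndarray, rng_seed: int, swap_factor: int = 10
) -> tuple[np.ndarray, bool]:
    """Degree-preserving randomization by double edge swaps.

    Attempts ``swap_factor * n_edges`` successful swaps. Returns the
    rewired adjacency and a flag that is True when the swap budget could
    not be met (e.g. a complete graph admits no legal swap), in which
    case the input is returned unchanged apart from any swaps achieved.
    """
    a = _check_binary(adjacency)
    n_edges = int(a.sum()) // 2
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    g = nx.from_numpy_array(a)
    nswap = swap_factor * n_edges
    exhausted = False
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=int(rng_seed))
    except nx.NetworkXAlgorithmError:
        exhausted = True
    out = nx.to_numpy_array(g, nodelist=range(a.shape[0]))
    return out, exhausted


def compute_small_world(
    adjacency: np.ndarray,
    n_null: int = 100,
    rng_seed: int = 0,
    swap_factor: int = 10,
) -> HemisphereMetrics:
    """gamma, lambda and sigma against ``n_null`` rewired null networks."""
    a = _check_binary(adjacency)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    cbar, length, disconnected = compute_global_metrics(a)

    seeds = np.random.SeedSequence(rng_seed).generate_state(n_null)
    c_rand = np.empty(n_null)
    l_rand = np.empty(n_null)
    n_exhausted = 0
    for i in range(n_null):
        null, exhausted = rewire_null(a, int(seeds[i] % (2**31)), swap_factor)
        n_exhausted += exhausted
        c_rand[i], l_rand[i], _ = compute_global_metrics(null)

    cbar_rand = float(c_rand.mean())
    length_rand = float(l_rand.mean())
    if cbar_rand == 0 or length_rand == 0:
        raise ValueError("degenerate null networks: zero mean clustering or length")
    gamma = cbar / cbar_rand
    lam = length / length_rand
    return HemisphereMetrics(
        mean_clustering=cbar,
        path_length=length,
        mean_clustering_rand=cbar_rand,
        path_length_rand=length_rand,
        gamma=gamma,
        lambda_=lam,
        sigma=gamma / lam,
        disconnected=disconnected,
        n_rewiring_exhausted=n_exhausted,
    )
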