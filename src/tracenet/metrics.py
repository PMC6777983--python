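"""Binary and weighted directed graph metrics.

Clustering follows the directed formulation of Fagiolo (2007), "total"
variant: all eight directed triangle motifs through a node count, and the
weighted version scores each triangle by the geometric mean (cube root of
the product) of its raw edge weights. No max-weight rescaling is applied,
so weighted clustering lives on the scale of the weights themselves.

Path lengths treat the inverse weight 1/w as the cost of traversing an
edge; the weighted characteristic path length L^w averages minimal costs
over ordered pairs and the characteristic step length Lstep^w averages the
hop counts those minimal-cost routes use (ties between equal-cost routes
resolved toward fewer hops, then lower node index, for determinism).
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .core import Connectome

logger = logging.getLogger("tracenet")

__all__ = [
    "MetricVector",
    "clustering_binary",
    "clustering_weighted",
    "path_length_binary",
    "path_length_weighted",
]


@dataclass
class MetricVector:
    """A per-node metric and its network-level aggregate."""

    name: str
    per_node: np.ndarray
    network_value: float


def _fagiolo_clustering(A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Directed clustering per node from adjacency A and weights W.

    With W == A this is the binary directed clustering; with the raw
    weights it is the weighted variant (cube-root weight products). The
    denominator counts possible directed triangles from A alone:
    d_tot(d_tot - 1) - 2 d_bidir.
    """
    A = A.astype(float)
    S = np.cbrt(W) + np.cbrt(W).T
    t = np.diag(S @ S @ S) / 2.0
    d_tot = A.sum(axis=0) + A.sum(axis=1)
    d_bidir = (A * A.T).sum(axis=1)
    denom = d_tot * (d_tot - 1) - 2 * d_bidir
    out = np.zeros(len(A))
    ok = denom > 0
    out[ok] = t[ok] / denom[ok]
    return out


def clustering_binary(c: Connectome) -> MetricVector:
    """Directed binary clustering coefficient C^b per node and its mean.

    Nodes with fewer than two neighbors have no possible triangle and
    contribute 0 to the network mean.
    """
    per_node = _fagiolo_clustering(c.A, c.A.astype(float))
    return MetricVector("clustering_binary", per_node, float(per_node.mean()))


def clustering_weighted(c: Connectome) -> MetricVector:
    """Directed weighted clustering coefficient C^w (Fagiolo), raw weights."""
    if np.any(c.W < 0):
        raise ValueError("weights must be non-negative")
    per_node = _fagiolo_clustering(c.A, c.W)
    return MetricVector("clustering_weighted", per_node, float(per_node.mean()))


def path_length_binary(c: Connectome) -> MetricVector:
    """Characteristic path length L^b: mean directed hop distance.

    Unreachable ordered pairs are excluded from the mean (and counted in a
    log message); per-node values are row means of the distance matrix.
    """
    D = shortest_path(c.A, method="D", unweighted=True, directed=True)
    return _pair_means(D, "path_length_binary")


def _pair_means(D: np.ndarray, name: str) -> MetricVector:
    n = len(D)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_unreachable = int(off.sum() - finite.sum())
    if n_unreachable:
        logger.warning("%s: %d unreachable ordered pairs excluded", name, n_unreachable)
    per_node = np.full(n, np.nan)
    for i in range(n):
        row = D[i, finite[i]]
        if row.size:
            per_node[i] = row.mean()
    network = float(D[finite].mean()) if finite.any() else float("nan")
    return MetricVector(name, per_node, network)


def _dijkstra_cost_hops(cost: np.ndarray, src: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-source shortest paths under lexicographic (cost, hops) order."""
    n = len(cost)
    dist = np.full(n, np.inf)
    hops = np.full(n, np.inf)
    dist[src], hops[src] = 0.0, 0
    heap = [(0.0, 0, src)]
    done = np.zeros(n, dtype=bool)
    nbrs = [np.flatnonzero(np.isfinite(cost[i])) for i in range(n)]
    while heap:
        d, h, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v in nbrs[u]:
            nd, nh = d + cost[u, v], h + 1
            if nd < dist[v] or (nd == dist[v] and nh < hops[v]):
                dist[v], hops[v] = nd, nh
                heapq.heappush(heap, (nd, nh, int(v)))
    return dist, hops


def path_length_weighted(c: Connectome) -> tuple[MetricVector, MetricVector]:
    """Weighted characteristic path length L^w and step length Lstep^w.

    Edge cost is the inverse connection strength 1/w. Returns the mean
    minimal travel cost over ordered pairs and the mean number of discrete
    steps those cost-minimal routes take (a measure of the binary
    efficiency of weighted routing).
    """
    if np.any((c.A > 0) & (c.W <= 0)):
        raise ValueError("zero-weight edge on the adjacency support")
    n = c.n_nodes
    cost = np.full((n, n), np.inf)
    on = c.A > 0
    cost[on] = 1.0 / c.W[on]
    D = np.empty((n, n))
    H = np.empty((n, n))
    for i in range(n):
        D[i], H[i] = _dijkstra_cost_hops(cost, i)
    lw = _pair_means(D, "path_length_weighted")
    lstep = _pair_means(H, "step_length_weighted")
    return lw, lstep
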