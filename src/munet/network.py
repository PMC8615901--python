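"""Minimum-spanning-tree backbone extraction and graph metrics.

Connectivity weights are mapped to lengths (reciprocal map, so the strongest
connections become the shortest distances; nonpositive weights are clipped to
a small epsilon), the MST is extracted with Kruskal's algorithm and its link
weights binarized.  Global efficiency (mean inverse shortest-path length) and
diameter (longest path, in edges) are computed on the binarized tree's
hop-count distance matrix; the normalized maximum betweenness centrality
(BCnorm) is computed on the full weighted length matrix by default, with an
MST-based variant available.  Smaller diameter / higher efficiency indicate a
more star-like, integrated backbone; BCnorm indexes hub overload.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "LengthMatrix",
    "MSTResult",
    "to_lengths",
    "kruskal_mst",
    "tree_distances",
    "global_efficiency",
    "diameter",
    "bc_norm",
    "mst_analysis",
    "metrics_table",
]

DEFAULT_EPSILON = 1e-6


class NetworkError(ValueError):
    pass


@dataclass
class LengthMatrix:
    """Symmetric nonnegative length matrix (larger weight => smaller length)."""

    values: np.ndarray
    n_clipped: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise NetworkError("length matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise NetworkError("length matrix must be symmetric")
        off = ~np.eye(n, dtype=bool)
        if np.any(self.values[off] <= 0):
            raise NetworkError("off-diagonal lengths must be positive")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class MSTResult:
    """Binarized spanning tree: edge list plus derived metrics."""

    edges: list[tuple[int, int]]
    n_nodes: int
    total_length: float = 0.0
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise NetworkError("a spanning tree has exactly n-1 edges")

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a


def to_lengths(weights, epsilon: float = DEFAULT_EPSILON, provenance: str = "") -> LengthMatrix:
    """Map a connectivity matrix to lengths: L_ij = 1 / max(W_ij, epsilon).

    The map is strictly monotone-decreasing on unclipped entries, so stronger
    connections get shorter lengths; nonpositive (e.g. negative DWPLI) and
    sub-epsilon entries are clipped and counted.
    """
    if epsilon <= 0:
        raise NetworkError("epsilon must be positive")
    W = np.asarray(getattr(weights, "values", weights), dtype=float)
    if not provenance and hasattr(weights, "subject"):
        provenance = f"{weights.subject}/{weights.condition}/{weights.emotion}"
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    clipped = int(np.count_nonzero((W <= epsilon) & off)) // 2
    L = np.zeros_like(W)
    L[off] = 1.0 / np.maximum(W[off], epsilon)
    return LengthMatrix(values=L, n_clipped=clipped, provenance=provenance)


def _as_length_values(L) -> np.ndarray:
    values = np.asarray(getattr(L, "values", L), dtype=float)
    if not np.all(np.isfinite(values)):
        raise NetworkError("length matrix must be finite (connected graph)")
    return values


def kruskal_mst(L) -> MSTResult:
    """Minimum spanning tree of a length matrix via Kruskal's algorithm.

    Ties are broken deterministically by (length, smaller node index, larger
    node index): edges are inserted in that order and Kruskal's stable sort
    preserves it within equal lengths.
    """
    values = _as_length_values(L)
    n = values.shape[0]
    if n < 2:
        raise NetworkError("need at least 2 nodes")
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, values[iu, ju]))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for k in order:
        g.add_edge(int(iu[k]), int(ju[k]), length=float(values[iu[k], ju[k]]))
    edges = [
        (min(u, v), max(u, v))
        for u, v, _ in nx.minimum_spanning_edges(g, algorithm="kruskal", weight="length")
    ]
    edges.sort()
    total = float(sum(values[i, j] for i, j in edges))
    return MSTResult(edges=edges, n_nodes=n, total_length=total)


def tree_distances(mst: MSTResult) -> np.ndarray:
    """Hop-count distance matrix of the binarized tree (BFS)."""
    adj = csr_array(mst.adjacency())
    D = shortest_path(adj, method="D", unweighted=True, directed=False)
    if not np.all(np.isfinite(D)):
        raise NetworkError("tree is not connected")
    return D.astype(float)


def global_efficiency(D: np.ndarray) -> float:
    """Mean inverse shortest-path length over all ordered pairs i != j."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(D[off] <= 0) or not np.all(np.isfinite(D[off])):
        raise NetworkError("distance matrix must be positive and finite off-diagonal")
    return float(np.mean(1.0 / D[off]))


def diameter(D: np.ndarray) -> float:
    """Longest shortest path (in edges for a binarized tree)."""
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise NetworkError("distance matrix must be finite")
    return float(D.max())


def bc_norm(L, on_mst: bool = False) -> float:
    """Maximum betweenness centrality normalized to [0, 1].

    By default betweenness is computed with weighted (Dijkstra) shortest
    paths on the full length matrix; with ``on_mst=True`` it is computed on
    the binarized MST instead.  networkx's normalization divides node
    betweenness by (n-1)(n-2)/2 for undirected graphs.
    """
    values = _as_length_values(L)
    n = values.shape[0]
    if n < 3:
        return 0.0
    if on_mst:
        g = nx.from_numpy_array(kruskal_mst(L).adjacency())
        bc = nx.betweenness_centrality(g, normalized=True)
    else:
        iu, ju = np.triu_indices(n, k=1)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_weighted_edges_from(
            zip(iu.tolist(), ju.tolist(), values[iu, ju].tolist()), weight="length"
        )
        bc = nx.betweenness_centrality(g, normalized=True, weight="length")
    return float(max(bc.values()))


def mst_analysis(weights, epsilon: float = DEFAULT_EPSILON) -> MSTResult:
    """Full backbone analysis of one connectivity matrix.

    Maps weights to lengths, extracts the Kruskal MST, and fills the metrics:
    ``global_efficiency`` and ``diameter`` on the binarized tree distances,
    ``bc_norm`` on the weighted length matrix.
    """
    L = to_lengths(weights, epsilon)
    mst = kruskal_mst(L)
    D = tree_distances(mst)
    mst.metrics = {
        "global_efficiency": global_efficiency(D),
        "diameter": diameter(D),
        "bc_norm": bc_norm(L),
    }
    return mst


def metrics_table(results: dict[tuple[str, str, str], MSTResult]) -> pd.DataFrame:
    """Metrics table: subject, condition, emotion, and the three MST metrics."""
    rows = []
    for (subject, condition, emotion), mst in sorted(results.items()):
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "emotion": emotion,
                **mst.metrics,
            }
        )
    return pd.DataFrame(rows)


def save_edge_list(mst: MSTResult, path) -> None:
    """Two-column text export of the binarized MST edges."""
    with open(path, "w") as fh:
        for i, j in mst.edges:
            fh.write(f"{i}\t{j}\n")
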