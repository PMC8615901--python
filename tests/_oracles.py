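"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: spanning trees are
enumerated via Prüfer sequences, betweenness by explicit path enumeration,
and the multiple-comparison procedures by their textbook definitions.
"""

from __future__ import annotations

import itertools

import numpy as np


def _decode_prufer_batch(seqs: np.ndarray, n: int) -> np.ndarray:
    """Decode a batch of Prüfer sequences to edge lists, shape (T, n-1, 2)."""
    T = seqs.shape[0]
    degree = np.ones((T, n), dtype=np.int32)
    for i in range(n - 2):
        np.add.at(degree, (np.arange(T), seqs[:, i]), 1)
    edges = np.empty((T, n - 1, 2), dtype=np.int32)
    alive = np.ones((T, n), dtype=bool)
    deg = degree.copy()
    for i in range(n - 2):
        s = seqs[:, i]
        leaf = np.argmax((deg == 1) & alive, axis=1)
        edges[:, i, 0] = leaf
        edges[:, i, 1] = s
        deg[np.arange(T), leaf] -= 1
        alive[np.arange(T), leaf] = False
        deg[np.arange(T), s] -= 1
    # the two remaining degree-1 nodes form the last edge
    rem = np.argsort(~((deg == 1) & alive), axis=1, kind="stable")[:, :2]
    edges[:, n - 2, :] = rem
    return edges


def all_spanning_tree_edges(n: int) -> np.ndarray:
    """Edge lists of every labelled spanning tree of K_n (Cayley: n^(n-2))."""
    if n == 2:
        return np.array([[[0, 1]]], dtype=np.int32)
    seqs = np.array(
        list(itertools.product(range(n), repeat=n - 2)), dtype=np.int32
    )
    return _decode_prufer_batch(seqs, n)


def min_spanning_tree_weight(L: np.ndarray, edges: np.ndarray | None = None) -> float:
    """Minimum total length over all spanning trees, by exhaustive enumeration."""
    n = L.shape[0]
    if edges is None:
        edges = all_spanning_tree_edges(n)
    weights = L[edges[..., 0], edges[..., 1]].sum(axis=1)
    return float(weights.min())


def floyd_warshall(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts on a binary adjacency matrix."""
    n = adjacency.shape[0]
    D = np.where(adjacency > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :])
    return D


def betweenness_by_enumeration(L: np.ndarray) -> np.ndarray:
    """Weighted-shortest-path betweenness per node by simple-path enumeration.

    Feasible for n <= 8.  Equal-length shortest paths split the credit.
    """
    n = L.shape[0]
    bc = np.zeros(n)
    nodes = list(range(n))
    for s, t in itertools.combinations(nodes, 2):
        best = np.inf
        best_paths: list[tuple[int, ...]] = []
        others = [v for v in nodes if v not in (s, t)]
        for k in range(len(others) + 1):
            for mid in itertools.permutations(others, k):
                path = (s, *mid, t)
                length = sum(L[a, b] for a, b in zip(path[:-1], path[1:]))
                if length < best - 1e-12:
                    best, best_paths = length, [path]
                elif abs(length - best) <= 1e-12:
                    best_paths.append(path)
        for path in best_paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(best_paths)
    return bc


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Textbook Holm step-down adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, m * p[idx] / (rank + 1))
        adj[idx] = running
    return adj
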