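"""k-nearest-neighbor graph construction with Jaccard edge re-weighting.

This is the graph half of PhenoGraph-style phenoclustering: an exact kNN
search, the directed neighbor lists symmetrized into an undirected edge set,
and each edge (u, v) weighted by the Jaccard coefficient of the two
endpoints' k-neighbor sets.  Edges whose neighbor sets are disjoint
(Jaccard 0) are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["KnnGraph", "build_knn_graph", "jaccard_coefficient"]

# full pairwise distances are used below this size so that distance ties are
# broken exactly by node index
_BRUTE_FORCE_MAX_N = 4096


@dataclass
class KnnGraph:
    """Undirected weighted graph; each edge is stored once with u < v."""

    n_nodes: int
    k: int
    edges: np.ndarray  # (E, 2) int
    weights: np.ndarray  # (E,) float in (0, 1]

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights length mismatch")
        if len(self.edges):
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            if (self.weights <= 0).any() or (self.weights > 1).any():
                raise ValueError("weights must lie in (0, 1]")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"u": self.edges[:, 0], "v": self.edges[:, 1], "weight": self.weights}
        ).to_csv(path, sep="\t", index=False)


def jaccard_coefficient(a, b) -> float:
    """|a ∩ b| / |a ∪ b| for two index sets."""
    a, b = set(a), set(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


if _HAVE_NUMBA:

    @njit(cache=True)
    def _intersection_sizes(nbrs, eu, ev):  # pragma: no cover - numba
        k = nbrs.shape[1]
        out = np.empty(eu.size, dtype=np.int64)
        for e in range(eu.size):
            a = nbrs[eu[e]]
            b = nbrs[ev[e]]
            i = 0
            j = 0
            c = 0
            while i < k and j < k:
                if a[i] == b[j]:
                    c += 1
                    i += 1
                    j += 1
                elif a[i] < b[j]:
                    i += 1
                else:
                    j += 1
            out[e] = c
        return out

else:  # pragma: no cover - numba is a hard dependency; kept for safety

    def _intersection_sizes(nbrs, eu, ev):
        k = nbrs.shape[1]
        out = np.empty(eu.size, dtype=np.int64)
        for e in range(eu.size):
            out[e] = np.intersect1d(nbrs[eu[e]], nbrs[ev[e]]).size
        return out


def _exact_knn(X: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors per row, ties broken by lowest node index."""
    n = X.shape[0]
    if n <= _BRUTE_FORCE_MAX_N:
        from sklearn.metrics import pairwise_distances

        D = pairwise_distances(X, metric="euclidean")
        np.fill_diagonal(D, np.inf)
        # lexicographic (distance, index): argsort is stable with kind="stable"
        order = np.argsort(D, axis=1, kind="stable")
        return order[:, :k]
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto", metric="euclidean")
    nn.fit(X)
    dist, idx = nn.kneighbors(X)
    # drop self; for duplicate points self may not be first
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k]
        if row.size < k:  # all k+1 were distinct of i (self beyond horizon)
            row = idx[i][:k]
        out[i] = row
    return out


def build_knn_graph(X, k: int, metric: str = "euclidean", seed: int = 0) -> KnnGraph:
    """Exact kNN graph with Jaccard-coefficient edge weights.

    Parameters
    ----------
    X : array-like (n_events, n_channels)
        Transformed event intensities.
    k : int
        Neighbor count; must satisfy ``k < n_events``.
    metric : {"euclidean"}
    seed : int
        Accepted for interface symmetry; construction is deterministic.

    Notes
    -----
    Distance ties are broken by node index (exactly so for inputs up to a
    few thousand events, where full pairwise distances are affordable).
    Zero-Jaccard edges are dropped.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    if k >= n:
        raise ValueError(f"k={k} must be < n_events={n}")
    if k < 1:
        raise ValueError("k must be >= 1")

    nbrs = _exact_knn(X, k)
    nbrs_sorted = np.sort(nbrs, axis=1)

    rows = np.repeat(np.arange(n, dtype=np.int64), k)
    cols = nbrs.reshape(-1).astype(np.int64)
    u = np.minimum(rows, cols)
    v = np.maximum(rows, cols)
    pairs = np.unique(np.stack([u, v], axis=1), axis=0)

    inter = _intersection_sizes(nbrs_sorted, pairs[:, 0], pairs[:, 1])
    union = 2 * k - inter
    w = inter / union
    keep = w > 0
    return KnnGraph(n_nodes=n, k=k, edges=pairs[keep], weights=w[keep])
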