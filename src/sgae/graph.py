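"""Spatial neighbor network (SNN) construction and normalization.

The SNN is a k-nearest-neighbor graph over spot coordinates, symmetrized by
union. It can be made "cell-type aware" by pruning edges whose endpoints fall
in different expression preclusters, and is normalized with self-loops as
Â = D̂^{-1/2}(A+I)D̂^{-1/2} for the graph-convolution layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import CoordinateTable, FeatureMatrix

__all__ = ["SpatialGraph", "NormalizedAdjacency", "build_knn_graph",
           "precluster_expression", "prune_by_precluster", "normalize_adjacency",
           "write_edge_list", "read_edge_list"]


@dataclass
class SpatialGraph:
    """Symmetric binary adjacency over spots (no stored self-loops)."""

    adjacency: sp.csr_matrix
    coords: CoordinateTable | None = None

    def __post_init__(self):
        a = sp.csr_matrix(self.adjacency)
        a.data = np.ones_like(a.data)
        a.setdiag(0)
        a.eliminate_zeros()
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def edges(self) -> np.ndarray:
        """Undirected edge list as an |E| x 2 array with i < j, lexicographic."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order]])

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2


@dataclass
class NormalizedAdjacency:
    """Â = D̂^{-1/2}(A+I)D̂^{-1/2}, with D̂ the degree matrix of A+I."""

    values: sp.csr_matrix

    def toarray(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def build_knn_graph(coords: CoordinateTable, k: int = 6) -> SpatialGraph:
    """Union-symmetrized Euclidean kNN graph over spot coordinates.

    Exact distance ties are broken toward the lower spot index so the graph
    is reproducible on gridded platforms.
    """
    xy = coords.xy
    n = xy.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < N, got k={k}, N={n}")
    rows, cols = [], []
    if n <= 4096:
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        for i in range(n):
            order = np.lexsort((np.arange(n), d2[i]))[:k]
            rows.extend([i] * k)
            cols.extend(order.tolist())
    else:
        from scipy.spatial import cKDTree

        tree = cKDTree(xy)
        _, idx = tree.query(xy, k=k + 1)
        for i in range(n):
            neigh = [j for j in idx[i] if j != i][:k]
            rows.extend([i] * len(neigh))
            cols.extend(neigh)
    a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    a = ((a + a.T) > 0).astype(np.float64)  # union symmetrization
    return SpatialGraph(a, coords=coords)


def precluster_expression(features: FeatureMatrix | np.ndarray,
                          method: str = "leiden",
                          resolution_or_k: float = 1.0,
                          seed: int = 0,
                          n_neighbors: int = 15) -> np.ndarray:
    """Pseudo-labels from expression features, for cell-type-aware pruning.

    'leiden' runs Leiden community detection on a kNN graph in feature space
    at the given resolution; 'kmeans' runs seeded K-means with
    round(resolution_or_k) clusters. Labels are 0..G-1 with every label used.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    n = x.shape[0]
    if method == "kmeans":
        from sklearn.cluster import KMeans

        k = int(round(resolution_or_k))
        if k > n:
            raise ValueError(f"requested {k} clusters for {n} spots")
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
    elif method == "leiden":
        import igraph
        import leidenalg
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=min(n_neighbors, n - 1) + 1).fit(x)
        _, idx = nn.kneighbors(x)
        edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
        g = igraph.Graph(n=n, edges=sorted(edges))
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(resolution_or_k), seed=int(seed))
        labels = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown preclustering method {method!r}")
    # compact to 0..G-1 in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels.astype(np.int64)


def prune_by_precluster(graph: SpatialGraph, labels: np.ndarray) -> SpatialGraph:
    """Keep edge (i, j) only when labels[i] == labels[j]."""
    labels = np.asarray(labels)
    if labels.shape[0] != graph.n_spots:
        raise ValueError("label vector length must equal number of spots")
    coo = graph.adjacency.tocoo()
    keep = labels[coo.row] == labels[coo.col]
    a = sp.csr_matrix((coo.data[keep], (coo.row[keep], coo.col[keep])),
                      shape=graph.adjacency.shape)
    return SpatialGraph(a, coords=graph.coords)


def normalize_adjacency(graph: SpatialGraph | sp.spmatrix | np.ndarray) -> NormalizedAdjacency:
    """Self-loop-augmented symmetric normalization of a binary adjacency."""
    a = graph.adjacency if isinstance(graph, SpatialGraph) else sp.csr_matrix(graph)
    n = a.shape[0]
    a_tilde = a + sp.eye(n, format="csr")
    d = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(d))
    return NormalizedAdjacency(sp.csr_matrix(d_inv_sqrt @ a_tilde @ d_inv_sqrt))


def write_edge_list(graph: SpatialGraph, path) -> None:
    """Write the undirected edge set as a 0-based (i, j) TSV with header."""
    edges = graph.edges()
    with open(path, "w") as fh:
        fh.write("i\tj\n")
        for i, j in edges:
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path, n_spots: int,
                   coords: CoordinateTable | None = None) -> SpatialGraph:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    a = sp.csr_matrix((np.ones(len(df)), (df["i"], df["j"])),
                      shape=(n_spots, n_spots))
    return SpatialGraph(a + a.T, coords=coords)
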