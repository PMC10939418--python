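"""Hard clustering of embeddings and spatial label refinement."""

from __future__ import annotations

import numpy as np

from .graph import SpatialGraph

__all__ = ["kmeans_with_centers", "kmeans_cluster", "refine_labels",
           "louvain_or_leiden_cluster"]


def kmeans_with_centers(h: np.ndarray, k: int, seed: int = 0,
                        n_init: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Seeded K-means (k-means++ init, best of `n_init` restarts).

    Clusters are relabeled so centers are ordered by ascending first
    coordinate, making the labeling deterministic given the seed.
    """
    from sklearn.cluster import KMeans

    h = np.asarray(h, dtype=np.float64)
    if not 1 <= k <= h.shape[0]:
        raise ValueError(f"k={k} incompatible with N={h.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed).fit(h)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    return km.cluster_centers_[order], relabel[km.labels_]


def kmeans_cluster(h: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Hard K-means labels of the embedding rows."""
    _, labels = kmeans_with_centers(h, k, seed)
    return labels


def refine_labels(labels: np.ndarray, graph: SpatialGraph,
                  n_iters: int = 1) -> np.ndarray:
    """Synchronous neighbor-majority relabeling (`n_iters` passes, default one).

    Each spot takes the most frequent label among its neighbors (its own
    label does not vote); ties and isolated spots keep the current label.
    Within a pass all updates read the pass-input labeling.
    """
    labels = np.asarray(labels)
    if n_iters > 1:
        for _ in range(n_iters):
            labels = refine_labels(labels, graph, 1)
        return labels
    if labels.shape[0] != graph.n_spots:
        raise ValueError("label vector length must equal number of spots")
    a = graph.adjacency
    out = labels.copy()
    indptr, indices = a.indptr, a.indices
    for i in range(graph.n_spots):
        neigh = indices[indptr[i]:indptr[i + 1]]
        if neigh.size == 0:
            continue
        vals, counts = np.unique(labels[neigh], return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        if winners.size == 1:
            out[i] = winners[0]
        # tie: keep the spot's current label
    return out


def louvain_or_leiden_cluster(h: np.ndarray, resolution: float = 1.0,
                              seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """Leiden community detection on a kNN graph built in embedding space."""
    from .graph import precluster_expression

    return precluster_expression(np.asarray(h), method="leiden",
                                 resolution_or_k=resolution, seed=seed,
                                 n_neighbors=n_neighbors)
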