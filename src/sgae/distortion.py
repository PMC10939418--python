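"""Graph distortion: the two corrupted views fed to the Siamese encoders.

View 1 pairs multiplicative-Gaussian-corrupted features with an edge-removed
adjacency (the lowest-cosine-similarity edges in the latent space deleted).
View 2 pairs an independent corruption with the Personalized-PageRank
diffusion of the normalized adjacency, A^d = α(I − (1−α)Â)^{-1}, which mixes
in higher-order neighborhoods (α is the teleport probability, default 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .graph import NormalizedAdjacency, SpatialGraph, normalize_adjacency

__all__ = ["DistortionConfig", "DistortedViewPair", "corrupt_features",
           "edge_removal_mask", "ppr_diffusion", "make_views"]

_DENSE_SOLVE_MAX_N = 5000


@dataclass
class DistortionConfig:
    noise_sd: float = 0.1        # s.d. of the multiplicative N(1, sd^2) noise
    drop_fraction: float = 0.10  # fraction of lowest-similarity edges removed
    alpha: float = 0.2           # PPR teleport probability


@dataclass
class DistortedViewPair:
    """Inputs to the Siamese encoders: (x1, a_m) and (x2, a_d)."""

    x1: np.ndarray
    x2: np.ndarray
    a_m: sp.csr_matrix   # normalized edge-removed adjacency
    a_d: np.ndarray      # PPR diffusion matrix (dense)


def corrupt_features(x: np.ndarray, noise_sd: float = 0.1,
                     seed: int | None = None) -> np.ndarray:
    """Hadamard-product corruption X̃ = X ⊙ N with N ~ N(1, noise_sd²) i.i.d."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    if noise_sd == 0:
        return x.copy()
    rng = np.random.default_rng(seed)
    return x * rng.normal(1.0, noise_sd, size=x.shape)


def _edge_cosines(h: np.ndarray, edges: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(h, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    hn = h / safe[:, None]
    hn[norms == 0] = 0.0  # zero rows get similarity 0 to every partner
    return np.einsum("ij,ij->i", hn[edges[:, 0]], hn[edges[:, 1]])


def edge_removal_mask(h: np.ndarray, graph: SpatialGraph,
                      drop_fraction: float = 0.10) -> SpatialGraph:
    """Delete the floor(drop_fraction·|E|) lowest-cosine-similarity edges.

    Similarity is between endpoint rows of the latent matrix `h`; ties are
    broken by lexicographic (i, j) order, lower removed first. The result
    stays symmetric.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    h = np.asarray(h, dtype=np.float64)
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite latent matrix")
    edges = graph.edges()  # already lexicographic
    n_drop = int(np.floor(drop_fraction * len(edges)))
    if n_drop == 0:
        return SpatialGraph(graph.adjacency.copy(), coords=graph.coords)
    sims = _edge_cosines(h, edges)
    drop = np.argsort(sims, kind="stable")[:n_drop]  # stable => lexicographic ties
    keep = np.ones(len(edges), dtype=bool)
    keep[drop] = False
    kept = edges[keep]
    n = graph.n_spots
    a = sp.csr_matrix((np.ones(len(kept)), (kept[:, 0], kept[:, 1])), shape=(n, n))
    return SpatialGraph(a + a.T, coords=graph.coords)


def ppr_diffusion(a_hat: NormalizedAdjacency | np.ndarray | sp.spmatrix,
                  alpha: float = 0.2) -> np.ndarray:
    """Personalized PageRank diffusion A^d = α(I − (1−α)Â)^{-1}.

    Exact dense solve up to N = 5000; sparse LU factorization with
    column-wise solves beyond.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    a = a_hat.values if isinstance(a_hat, NormalizedAdjacency) else a_hat
    n = a.shape[0]
    if alpha == 1.0:
        return np.eye(n)
    if n <= _DENSE_SOLVE_MAX_N:
        a_dense = np.asarray(a.todense()) if sp.issparse(a) else np.asarray(a)
        system = np.eye(n) - (1.0 - alpha) * a_dense
        try:
            out = alpha * scipy.linalg.solve(system, np.eye(n))
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover
            cond = np.linalg.cond(system)
            raise FloatingPointError(
                f"PPR system singular (condition number {cond:.3g})") from exc
    else:  # pragma: no cover - large-N path
        from scipy.sparse.linalg import splu

        system = (sp.eye(n) - (1.0 - alpha) * sp.csc_matrix(a)).tocsc()
        lu = splu(system)
        out = alpha * lu.solve(np.eye(n))
    return out


def make_views(x: np.ndarray, graph: SpatialGraph, h_pre: np.ndarray,
               config: DistortionConfig | None = None, seed: int = 0,
               a_d: np.ndarray | None = None) -> DistortedViewPair:
    """Assemble both distorted views.

    `h_pre` is the latent matrix used to rank edges for removal (raw features
    bootstrap the first call, the most recent fused embedding thereafter).
    `a_d` may carry a precomputed diffusion matrix since it depends only on
    the clean graph and α.
    """
    config = config or DistortionConfig()
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s) for s in ss.generate_state(2) >> 1)  # keep below 2^31
    x1 = corrupt_features(x, config.noise_sd, seed=s1)
    x2 = corrupt_features(x, config.noise_sd, seed=s2)
    masked = edge_removal_mask(h_pre, graph, config.drop_fraction)
    a_m = normalize_adjacency(masked).values
    if a_d is None:
        a_d = ppr_diffusion(normalize_adjacency(graph), config.alpha)
    return DistortedViewPair(x1=x1, x2=x2, a_m=a_m, a_d=a_d)
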