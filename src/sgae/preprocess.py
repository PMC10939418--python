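"""Expression preprocessing: library-size normalization, log transform, PCA.

Per spot the counts are scaled to a common library size (the median spot
total by default), log1p-transformed, and reduced to the top principal
components, which serve as the model's input features.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.decomposition import PCA

from .io import CountMatrix, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["normalize_and_log", "pca_reduce"]


def normalize_and_log(counts: CountMatrix,
                      target_sum: float | str = "median") -> CountMatrix:
    """Scale each spot to `target_sum` total counts, then log1p.

    Row i becomes log(1 + target_sum * x_i / sum_j x_ij). Spots whose total
    count is zero cannot be normalized and are dropped with a warning.
    """
    x = np.asarray(counts.values, dtype=np.float64)
    totals = x.sum(axis=1)
    if np.all(totals == 0):
        raise ValueError("all spots have zero total counts")
    keep = totals > 0
    if not np.all(keep):
        dropped = [s for s, k in zip(counts.spot_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-count spot(s): {dropped[:5]}")
        logger.warning("dropping %d zero-count spots", len(dropped))
        x, totals = x[keep], totals[keep]
    if target_sum == "median":
        target = float(np.median(totals))
    else:
        target = float(target_sum)
        if target <= 0:
            raise ValueError("target_sum must be positive")
    out = np.log1p(x * (target / totals)[:, None])
    return CountMatrix(out, [s for s, k in zip(counts.spot_ids, keep) if k],
                       list(counts.gene_ids))


def pca_reduce(logcounts: np.ndarray | CountMatrix, n_components: int = 50,
               seed: int = 0) -> FeatureMatrix:
    """Top principal components of the (internally centered) expression matrix.

    Components are ordered by decreasing explained variance. Each component's
    sign is fixed so its largest-magnitude gene loading is positive, making
    the output deterministic across solver runs. The exact solver is used up
    to min(N, D) = 2000, the seeded randomized solver beyond.
    """
    x = logcounts.values if isinstance(logcounts, CountMatrix) else np.asarray(logcounts)
    x = np.asarray(x, dtype=np.float64)
    n, d = x.shape
    if not 1 <= n_components <= min(n, d):
        raise ValueError(f"n_components={n_components} exceeds min(N, D)={min(n, d)}")
    solver = "full" if min(n, d) <= 2000 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(x)
    # sign convention: largest-|loading| coordinate of each component positive
    flip = np.sign(pca.components_[np.arange(n_components),
                                   np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    fm = FeatureMatrix(scores * flip)
    fm.explained_variance_ratio = pca.explained_variance_ratio_
    return fm
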