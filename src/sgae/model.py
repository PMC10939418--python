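"""High-level modelling interface.

:class:`SGAE` bundles the full pipeline — preprocessing, spatial-graph
construction, cell-type-aware pruning, Siamese-autoencoder training, and
clustering — behind a statsmodels-style Model/Results pair::

    model = SGAE(counts, coords, n_clusters=3)
    res = model.fit(seed=0)
    print(res.summary())
    res.evaluate(truth)            # ARI / NMI / FMI / AMI / Moran's I
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .clustering import refine_labels as _refine
from .distortion import DistortionConfig
from .graph import (SpatialGraph, build_knn_graph, precluster_expression,
                    prune_by_precluster)
from .io import CountMatrix, CoordinateTable, read_coords, read_counts, read_labels
from .preprocess import normalize_and_log, pca_reduce
from .train import TrainConfig, infer, init_centers, init_params, pretrain, train

logger = logging.getLogger(__name__)

__all__ = ["SGAE", "SGAEResults"]


class SGAE:
    """Siamese graph autoencoder for spatial-domain clustering.

    Parameters
    ----------
    counts
        Raw spots × genes counts.
    coords
        Spot coordinates; realigned to the count matrix by spot id.
    n_clusters
        Target number of spatial domains K.
    k_neighbors
        Spatial kNN degree of the SNN (default 6, suited to array platforms).
    prune
        Apply cell-type-aware pruning of the SNN using expression preclusters.
    use_pca, n_components
        Reduce log-expression to the top principal components (default 50)
        before encoding; `use_pca=False` feeds full log-expression.
    refine
        Run one neighbor-majority refinement pass on the final labels
        (intended for low-resolution array platforms).
    """

    def __init__(self, counts: CountMatrix, coords: CoordinateTable,
                 n_clusters: int, *,
                 k_neighbors: int = 6,
                 prune: bool = True,
                 precluster_method: str = "auto",
                 precluster_resolution: float = 1.0,
                 use_pca: bool = True,
                 n_components: int = 50,
                 target_sum: float | str = "median",
                 refine: bool = False,
                 train_config: TrainConfig | None = None,
                 **train_kwargs):
        self.counts = counts
        self.coords = coords.aligned_to(counts.spot_ids)
        self.n_clusters = int(n_clusters)
        self.k_neighbors = int(k_neighbors)
        self.prune = bool(prune)
        self.precluster_method = precluster_method
        self.precluster_resolution = float(precluster_resolution)
        self.use_pca = bool(use_pca)
        self.n_components = int(n_components)
        self.target_sum = target_sum
        self.refine = bool(refine)
        if train_config is None:
            train_config = TrainConfig(n_clusters=self.n_clusters, **train_kwargs)
        self.train_config = replace(train_config, n_clusters=self.n_clusters)

    # -- constructors ---------------------------------------------------------
    @classmethod
    def from_files(cls, counts_path, coords_path, n_clusters: int, *,
                   format: str = "csv", labels_path=None, **kwargs) -> "SGAE":
        counts = read_counts(counts_path, format=format,
                             **{k: kwargs.pop(k) for k in
                                ("spot_file", "gene_file", "orientation")
                                if k in kwargs})
        coords = read_coords(coords_path)
        model = cls(counts, coords, n_clusters, **kwargs)
        if labels_path is not None:
            model.truth = read_labels(labels_path, counts.spot_ids)
        return model

    @classmethod
    def from_synthetic(cls, dataset, n_clusters: int | None = None, **kwargs) -> "SGAE":
        k = dataset.spec.n_domains if n_clusters is None else n_clusters
        model = cls(dataset.counts, dataset.coords, k, **kwargs)
        model.truth = dataset.truth
        return model

    truth: np.ndarray | None = None

    # -- pipeline -------------------------------------------------------------
    def prepare(self, seed: int = 0):
        """Preprocess expression, build and (optionally) prune the SNN.

        Returns (features, training_graph, snn) where `snn` is the unpruned
        spatial graph used for refinement and Moran's I.
        """
        logged = normalize_and_log(self.counts, self.target_sum)
        coords = self.coords.aligned_to(logged.spot_ids)
        if self.use_pca:
            n_comp = min(self.n_components, logged.n_spots - 1, logged.n_genes)
            features = pca_reduce(logged, n_components=n_comp, seed=seed).values
        else:
            features = logged.values
        snn = build_knn_graph(coords, self.k_neighbors)
        graph = snn
        if self.prune:
            method = self.precluster_method
            if method == "auto":
                method = "leiden" if logged.n_spots >= 500 else "kmeans"
            res = (self.precluster_resolution if method == "leiden"
                   else self.n_clusters)
            pre = precluster_expression(features, method=method,
                                        resolution_or_k=res, seed=seed)
            graph = prune_by_precluster(snn, pre)
        return features, graph, snn

    def fit(self, seed: int = 0) -> "SGAEResults":
        """Run pretraining, center initialization, joint training, and inference."""
        config = replace(self.train_config, seed=int(seed))
        features, graph, snn = self.prepare(seed=seed)
        params = init_params(features.shape[1], config)
        params, emb, pre_history = pretrain(features, graph, params, config)
        centers, _ = init_centers(emb.h, config.n_clusters, seed=config.seed)
        run = train(features, graph, params, centers, config)
        history = pd.concat([pre_history, run.loss_history], ignore_index=True)
        refined = _refine(run.labels, snn) if self.refine else None
        return SGAEResults(model=self, params=params, config=config,
                           embedding=run.embedding, labels=run.labels,
                           refined_labels=refined, loss_history=history,
                           centers=run.centers, q_soft=run.q_soft,
                           graph=graph, snn=snn, spot_ids=list(self.coords.spot_ids)
                           if len(self.coords.spot_ids) == run.embedding.shape[0]
                           else None)


@dataclass
class SGAEResults:
    """Fitted embeddings, domain labels, and diagnostics."""

    model: SGAE
    params: object
    config: TrainConfig
    embedding: np.ndarray
    labels: np.ndarray
    refined_labels: np.ndarray | None
    loss_history: pd.DataFrame
    centers: np.ndarray
    q_soft: np.ndarray
    graph: SpatialGraph
    snn: SpatialGraph
    spot_ids: list | None = None

    @property
    def final_labels(self) -> np.ndarray:
        return self.labels if self.refined_labels is None else self.refined_labels

    def evaluate(self, truth=None) -> dict:
        """ARI/NMI/FMI/AMI against `truth` plus per-cluster Moran's I on the SNN."""
        labels = self.final_labels
        weights = _metrics.SpatialWeightMatrix.from_adjacency(self.snn.adjacency)
        moran = _metrics.per_cluster_moran(labels, weights)
        out = {"n_spots": int(labels.size),
               "n_clusters": int(np.unique(labels).size),
               "per_cluster_moran": [float(v) for v in moran]}
        truth = self.model.truth if truth is None else truth
        if truth is not None:
            out.update(ari=_metrics.ari(truth, labels),
                       nmi=_metrics.nmi(truth, labels),
                       fmi=_metrics.fmi(truth, labels),
                       ami=_metrics.ami(truth, labels))
        return out

    def summary(self) -> str:
        ev = self.evaluate()
        last = self.loss_history.iloc[-1]
        lines = [
            "Siamese graph autoencoder — spatial domain clustering",
            "=" * 56,
            f"spots: {ev['n_spots']}   latent dim: {self.embedding.shape[1]}"
            f"   clusters: {ev['n_clusters']}",
            f"epochs: {int((self.loss_history['phase'] == 'pretrain').sum())} pretrain"
            f" + {int((self.loss_history['phase'] == 'train').sum())} joint",
            f"final losses: rec_f={last['rec_f']:.4f} rec_a={last['rec_a']:.4f}"
            f" rr={last.get('rr', float('nan')):.4f}"
            f" clustering={last.get('clustering', float('nan')):.4f}",
            "median per-cluster Moran's I: "
            f"{np.nanmedian(ev['per_cluster_moran']):.4f}",
        ]
        if "ari" in ev:
            lines.append(f"vs ground truth: ARI={ev['ari']:.4f} NMI={ev['nmi']:.4f}"
                         f" FMI={ev['fmi']:.4f} AMI={ev['ami']:.4f}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write labels.csv, embedding.csv, loss_history.csv, run_config.json,
        and metrics.json (when ground truth is available)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ids = self.spot_ids or [f"spot{i}" for i in range(self.labels.size)]
        lab = pd.DataFrame({"spot_id": ids, "label": self.labels})
        lab["refined_label"] = (self.refined_labels if self.refined_labels
                                is not None else self.labels)
        lab.to_csv(outdir / "labels.csv", index=False)
        emb = pd.DataFrame(self.embedding, index=ids)
        emb.index.name = "spot_id"
        emb.to_csv(outdir / "embedding.csv")
        self.loss_history.to_csv(outdir / "loss_history.csv", index=False)
        cfg = asdict(self.config)
        cfg["encoder_dims"] = list(cfg["encoder_dims"])
        (outdir / "run_config.json").write_text(json.dumps(cfg, indent=2,
                                                           default=str))
        ev = self.evaluate()
        (outdir / "metrics.json").write_text(json.dumps(ev, indent=2))

    def plot_domains(self, path=None, use_refined: bool = True):
        """Scatter the spots colored by domain label."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        labels = self.final_labels if use_refined else self.labels
        xy = self.snn.coords.xy if self.snn.coords is not None else None
        if xy is None:
            raise ValueError("no coordinates attached to the graph")
        fig, ax = plt.subplots(figsize=(5, 5))
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=labels, cmap="tab10", s=12)
        ax.set_aspect("equal")
        ax.set_title("spatial domains")
        fig.colorbar(sc, ax=ax, shrink=0.8)
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig
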