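"""Training orchestration: pretraining, center initialization, joint training.

Training is full batch and runs in three stages:

1. **Pretrain** — minimize reconstruction (+ redundancy-reduction) loss on
   freshly distorted views each epoch.
2. **Center initialization** — K-means on the pretrained fused embedding
   gives the initial cluster centers of the clustering-guidance module.
3. **Joint training** — minimize L_REC + L_RR + L_C with the centers as
   trainable parameters; the self-training target P is refreshed from the
   current soft assignment every `target_update_interval` epochs.

Inference is a single clean forward pass (no feature noise, no edge
removal) whose fused embedding is clustered by K-means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import nn
from .autograd import Tensor
from .clustering import kmeans_with_centers
from .distortion import DistortionConfig, make_views, ppr_diffusion
from .graph import SpatialGraph, normalize_adjacency
from .nn import Adam, DecoderParams, EmbeddingSet, EncoderParams

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "ModelParams", "RunResult", "init_params",
           "pretrain", "init_centers", "train", "infer",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    n_clusters: int = 2
    pretrain_epochs: int = 100
    train_epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    target_update_interval: int = 5
    loss_weights: dict = field(default_factory=dict)  # rec_f/rec_a/rr/clustering
    encoder_dims: tuple = (256, 64)  # hidden sizes then latent; decoder mirrored
    fuse_weight: float = 0.5
    nu: float = 1.0
    distortion: DistortionConfig = field(default_factory=DistortionConfig)
    freeze_edge_mask: bool = False   # reuse the pretraining-end edge mask ranking
    pretrain_rr: bool = True         # include L_RR during pretraining
    rec_f_raw_adjacency: bool = False  # reconstruct AX with raw binary A, not Â
    final_kmeans: bool = True        # cluster the inferred embedding with K-means
    early_stop_patience: int | None = None

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.pretrain_epochs < 0 or self.train_epochs < 0:
            raise ValueError("epoch counts must be non-negative")


@dataclass
class ModelParams:
    encoder: EncoderParams
    decoder: DecoderParams
    fuse_weight: float = 0.5

    def tensors(self):
        return self.encoder.tensors() + self.decoder.tensors()


@dataclass
class RunResult:
    embedding: np.ndarray
    labels: np.ndarray
    loss_history: pd.DataFrame
    centers: np.ndarray
    q_soft: np.ndarray
    refined_labels: np.ndarray | None = None
    config: TrainConfig | None = None


def init_params(d_in: int, config: TrainConfig, seed: int | None = None) -> ModelParams:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dims = [d_in, *config.encoder_dims]
    enc = EncoderParams.init(dims, rng)
    dec = DecoderParams.init(list(reversed(dims)), rng)
    return ModelParams(encoder=enc, decoder=dec, fuse_weight=config.fuse_weight)


def _norm_dense_with_self_loops(a: np.ndarray) -> np.ndarray:
    """D̂^{-1/2}(A+I)D̂^{-1/2} for a dense non-negative matrix, D̂ from A+I."""
    at = a + np.eye(a.shape[0])
    d = at.sum(axis=1)
    inv = 1.0 / np.sqrt(d)
    return at * inv[:, None] * inv[None, :]


class _Workspace:
    """Per-run constants: clean operators, diffusion matrix, seeds."""

    def __init__(self, x: np.ndarray, graph: SpatialGraph, config: TrainConfig):
        self.x = np.asarray(x, dtype=np.float64)
        self.graph = graph
        self.config = config
        self.a_hat_clean = normalize_adjacency(graph).values
        self.a_binary = graph.adjacency
        self.a_d = ppr_diffusion(normalize_adjacency(graph), config.distortion.alpha)
        self.a_d_hat = _norm_dense_with_self_loops(self.a_d)
        self.a_binary_dense = np.asarray(self.a_binary.todense())
        self.rec_f_operator = (self.a_binary_dense if config.rec_f_raw_adjacency
                               else self.a_hat_clean)

    def epoch_views(self, h_latest: np.ndarray, epoch_seed: int):
        return make_views(self.x, self.graph, h_latest,
                          self.config.distortion, seed=epoch_seed, a_d=self.a_d)


def _forward(ws: _Workspace, params: ModelParams, views) -> dict:
    h1 = nn.encode(views.x1, views.a_m, params.encoder)
    h2 = nn.encode(views.x2, ws.a_d_hat, params.encoder)
    h = nn.fuse(h1, h2, params.fuse_weight)
    h_hat = nn.decode_features(h, ws.a_hat_clean, params.decoder)
    a_rec = nn.decode_adjacency(h)
    return {"h1": h1, "h2": h2, "h": h, "h_hat": h_hat, "a_rec": a_rec}


def _losses(ws: _Workspace, fwd: dict, with_rr: bool) -> dict:
    parts = {
        "rec_f": nn.loss_rec_f(ws.rec_f_operator, ws.x, fwd["h_hat"]),
        "rec_a": nn.loss_rec_a(ws.a_binary_dense, fwd["a_rec"]),
    }
    if with_rr:
        s_n = nn.cross_view_sample_corr(fwd["h1"], fwd["h2"])
        s_f = nn.cross_view_feature_corr(fwd["h1"], fwd["h2"])
        parts["rr"] = nn.loss_rr(s_n, s_f)
    return parts


def _check_finite_loss(value: float, epoch: int, term: str) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"loss term {term!r} diverged at epoch {epoch}")


def _epoch_seeds(base_seed: int, n: int, salt: int) -> list[int]:
    ss = np.random.SeedSequence([base_seed, salt])
    return [int(s) for s in (ss.generate_state(max(n, 1)) >> 1)]


def pretrain(x: np.ndarray, graph: SpatialGraph, params: ModelParams,
             config: TrainConfig) -> tuple[ModelParams, EmbeddingSet, pd.DataFrame]:
    """Reconstruction (+ redundancy-reduction) pretraining; returns final embedding."""
    ws = _Workspace(x, graph, config)
    opt = Adam(params.tensors(), lr=config.learning_rate)
    seeds = _epoch_seeds(config.seed, config.pretrain_epochs, salt=1)
    h_latest = ws.x  # raw features bootstrap the first edge-removal ranking
    rows = []
    for epoch in range(config.pretrain_epochs):
        views = ws.epoch_views(h_latest, seeds[epoch])
        fwd = _forward(ws, params, views)
        parts = _losses(ws, fwd, with_rr=config.pretrain_rr)
        total = nn.total_loss(parts, config.loss_weights)
        _check_finite_loss(total.item(), epoch, "total")
        opt.zero_grad()
        total.backward()
        opt.step()
        row = {"phase": "pretrain", "epoch": epoch,
               **{k: v.item() for k, v in parts.items()}, "total": total.item()}
        rows.append(row)
        logger.info("pretrain epoch %d: %s", epoch,
                    {k: round(v, 6) for k, v in row.items() if k not in ("phase",)})
        if not config.freeze_edge_mask:
            h_latest = fwd["h"].data
    emb = infer(x, graph, params, workspace=ws)
    history = pd.DataFrame(rows)
    return params, emb, history


def init_centers(h: np.ndarray, k: int, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """K-means over the pretrained embedding; centers sorted by first coordinate."""
    return kmeans_with_centers(h, k, seed, n_init=20)


def train(x: np.ndarray, graph: SpatialGraph, params: ModelParams,
          centers: np.ndarray, config: TrainConfig) -> RunResult:
    """Joint optimization of L_REC + L_RR + L_C with trainable cluster centers."""
    ws = _Workspace(x, graph, config)
    centers_t = Tensor(np.asarray(centers, dtype=np.float64), requires_grad=True)
    opt = Adam(params.tensors() + [centers_t], lr=config.learning_rate)
    seeds = _epoch_seeds(config.seed, config.train_epochs, salt=2)
    emb0 = infer(x, graph, params, workspace=ws)
    h_latest = emb0.h
    # optional anchor toward the pretrained cluster structure (weight 0 default)
    kl_pre_weight = float(config.loss_weights.get("kl_pretrained", 0.0))
    p_pretrained = nn.target_distribution(
        nn.soft_assignment(emb0.h, centers_t.data, config.nu).data)
    p_target = None
    rows = []
    best = np.inf
    stale = 0
    q_data = nn.soft_assignment(emb0.h, centers_t.data, config.nu).data
    for epoch in range(config.train_epochs):
        views = ws.epoch_views(h_latest, seeds[epoch])
        fwd = _forward(ws, params, views)
        parts = _losses(ws, fwd, with_rr=True)
        q = nn.soft_assignment(fwd["h"], centers_t, config.nu)
        if epoch % config.target_update_interval == 0 or p_target is None:
            p_target = nn.target_distribution(q.data)
        parts["clustering"] = nn.loss_clustering(p_target, q)
        if kl_pre_weight > 0:
            parts["kl_pretrained"] = nn.loss_clustering(p_pretrained, q)
        total = nn.total_loss(parts, config.loss_weights)
        _check_finite_loss(total.item(), epoch, "total")
        opt.zero_grad()
        total.backward()
        opt.step()
        q_data = q.data
        row = {"phase": "train", "epoch": epoch,
               **{k: v.item() for k, v in parts.items()}, "total": total.item()}
        rows.append(row)
        logger.info("train epoch %d: %s", epoch,
                    {k: round(v, 6) for k, v in row.items() if k != "phase"})
        if not config.freeze_edge_mask:
            h_latest = fwd["h"].data
        if config.early_stop_patience is not None:
            if total.item() < best - 1e-9:
                best, stale = total.item(), 0
            else:
                stale += 1
                if stale >= config.early_stop_patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    emb = infer(x, graph, params, workspace=ws)
    q_final = nn.soft_assignment(emb.h, centers_t.data, config.nu).data
    if config.final_kmeans:
        _, labels = kmeans_with_centers(emb.h, config.n_clusters, config.seed,
                                        n_init=20)
    else:
        labels = q_final.argmax(axis=1)
    return RunResult(embedding=emb.h, labels=labels,
                     loss_history=pd.DataFrame(rows), centers=centers_t.data,
                     q_soft=q_final, config=config)


def infer(x: np.ndarray, graph: SpatialGraph, params: ModelParams,
          workspace: _Workspace | None = None,
          config: TrainConfig | None = None) -> EmbeddingSet:
    """Clean forward pass: no feature noise, no edge removal."""
    if workspace is None:
        workspace = _Workspace(x, graph, config or TrainConfig())
    h1 = nn.encode(workspace.x, workspace.a_hat_clean, params.encoder)
    h2 = nn.encode(workspace.x, workspace.a_d_hat, params.encoder)
    h = nn.fuse(h1, h2, params.fuse_weight)
    return EmbeddingSet(h1=h1.data, h2=h2.data, h=h.data)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: ModelParams, config: TrainConfig,
                    rng_state: dict | None = None) -> None:
    """Serialize all weight matrices plus config into a single npz container."""
    arrays = {}
    for i, t in enumerate(params.encoder.w1):
        arrays[f"enc_w1_{i}"] = t.data
    for i, t in enumerate(params.encoder.w2):
        arrays[f"enc_w2_{i}"] = t.data
    for i, t in enumerate(params.encoder.b):
        arrays[f"enc_b_{i}"] = t.data
    for i, t in enumerate(params.decoder.w):
        arrays[f"dec_w_{i}"] = t.data
    cfg = {k: v for k, v in vars(config).items() if k != "distortion"}
    cfg["distortion"] = vars(config.distortion)
    cfg["fuse_weight_param"] = params.fuse_weight
    cfg["n_encoder_layers"] = params.encoder.n_layers
    cfg["n_decoder_layers"] = len(params.decoder.w)
    cfg["rng_state"] = rng_state
    meta = json.dumps(cfg, default=lambda o: list(o) if isinstance(o, tuple) else o)
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[ModelParams, TrainConfig]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        enc = EncoderParams(
            w1=[Tensor(z[f"enc_w1_{i}"], True) for i in range(meta["n_encoder_layers"])],
            w2=[Tensor(z[f"enc_w2_{i}"], True) for i in range(meta["n_encoder_layers"])],
            b=[Tensor(z[f"enc_b_{i}"], True) for i in range(meta["n_encoder_layers"])],
        )
        dec = DecoderParams(
            w=[Tensor(z[f"dec_w_{i}"], True) for i in range(meta["n_decoder_layers"])])
    dist = DistortionConfig(**meta.pop("distortion"))
    fuse_weight = meta.pop("fuse_weight_param")
    for k in ("n_encoder_layers", "n_decoder_layers", "rng_state"):
        meta.pop(k, None)
    meta["encoder_dims"] = tuple(meta["encoder_dims"])
    config = TrainConfig(distortion=dist, **meta)
    return ModelParams(encoder=enc, decoder=dec, fuse_weight=fuse_weight), config
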