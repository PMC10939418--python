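"""Siamese graph-autoencoder layers and loss terms.

The encoder stacks two-branch graph-convolution layers,

    H^(l) = sigma(A_view H^(l-1) W1^(l)) + sigma(H^(l-1) W2^(l) + b^(l)),

with one parameter set shared by both views (the Siamese constraint). The
feature decoder is a plain GCN on the undistorted normalized adjacency, and
the adjacency decoder is the squashed inner product H H^T. Training minimizes

    L = L_REC-F + L_REC-A + L_RR + L_C

where L_RR pushes the node-level and feature-level cross-view cosine
correlation matrices toward identity (Barlow-Twins-style redundancy
reduction) and L_C is the deep-embedded-clustering KL self-training term on
a Student's-t soft assignment.

All functions accept numpy arrays or :class:`~sgae.autograd.Tensor` and
return Tensors; use ``.data`` for the plain array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import ACTIVATIONS, Tensor, as_tensor, relu, sigmoid, spmm

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class EncoderParams:
    """Shared Siamese encoder weights: graph branch W1, residual branch W2, bias b."""

    w1: list
    w2: list
    b: list
    activation: str = "relu"  # hidden layers; final layer is linear

    @classmethod
    def init(cls, dims: list[int], rng: np.random.Generator,
             activation: str = "relu") -> "EncoderParams":
        w1, w2, b = [], [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            w1.append(Tensor(_glorot(rng, d_in, d_out), requires_grad=True))
            w2.append(Tensor(_glorot(rng, d_in, d_out), requires_grad=True))
            b.append(Tensor(np.zeros(d_out), requires_grad=True))
        return cls(w1=w1, w2=w2, b=b, activation=activation)

    @property
    def n_layers(self) -> int:
        return len(self.w1)

    def tensors(self) -> list[Tensor]:
        return [*self.w1, *self.w2, *self.b]


@dataclass
class DecoderParams:
    """GCN feature-decoder weights mapping latent q back to feature dim d."""

    w: list
    activation: str = "relu"

    @classmethod
    def init(cls, dims: list[int], rng: np.random.Generator,
             activation: str = "relu") -> "DecoderParams":
        w = [Tensor(_glorot(rng, i, o), requires_grad=True)
             for i, o in zip(dims[:-1], dims[1:])]
        return cls(w=w, activation=activation)

    def tensors(self) -> list[Tensor]:
        return list(self.w)


@dataclass
class EmbeddingSet:
    """Per-view embeddings H1, H2 and the fused embedding H."""

    h1: np.ndarray
    h2: np.ndarray
    h: np.ndarray


# ---------------------------------------------------------------------------
# Forward operations
# ---------------------------------------------------------------------------

def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")


def encoder_layer(h_prev, a_view, w1, w2, b, sigma="relu") -> Tensor:
    """One two-branch encoder layer: sigma(A h W1) + sigma(h W2 + b).

    The graph branch carries no bias; the residual (non-graph) branch does.
    """
    act = ACTIVATIONS[sigma] if isinstance(sigma, str) else sigma
    h_prev = as_tensor(h_prev)
    graph_branch = act(spmm(a_view, h_prev) @ as_tensor(w1))
    residual_branch = act(h_prev @ as_tensor(w2) + as_tensor(b))
    return graph_branch + residual_branch


def encode(x_view, a_view, params: EncoderParams) -> Tensor:
    """Stack encoder layers; hidden layers use params.activation, last is linear."""
    x_view = as_tensor(x_view)
    _check_finite(x_view.data, "x_view")
    h = x_view
    for layer in range(params.n_layers):
        sigma = params.activation if layer < params.n_layers - 1 else "identity"
        h = encoder_layer(h, a_view, params.w1[layer], params.w2[layer],
                          params.b[layer], sigma)
    return h


def fuse(h1, h2, weight: float = 0.5) -> Tensor:
    """Linear combination of the two view embeddings: w*H1 + (1-w)*H2."""
    h1, h2 = as_tensor(h1), as_tensor(h2)
    if h1.shape != h2.shape:
        raise ValueError(f"shape mismatch: {h1.shape} vs {h2.shape}")
    return h1 * weight + h2 * (1.0 - weight)


def decode_features(h, a_hat, params: DecoderParams) -> Tensor:
    """GCN decoder on the undistorted normalized adjacency: H^(k) = sigma(Â H W)."""
    h = as_tensor(h)
    for layer, w in enumerate(params.w):
        sigma = params.activation if layer < len(params.w) - 1 else "identity"
        act = ACTIVATIONS[sigma]
        h = act(spmm(a_hat, h) @ w)
    return h


def decode_adjacency(h, squash: bool = True) -> Tensor:
    """Adjacency reconstruction s(H H^T); logistic squashing keeps entries in (0,1)."""
    h = as_tensor(h)
    inner = h @ h.T
    return sigmoid(inner) if squash else inner


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def loss_rec_f(a_hat, x, h_hat) -> Tensor:
    """Feature reconstruction (1/2N)||Â X − Ĥ||_F²; target is neighbor-aggregated X."""
    x = np.asarray(x, dtype=np.float64)
    h_hat = as_tensor(h_hat)
    target = np.asarray(a_hat @ x)
    if target.shape != h_hat.shape:
        raise ValueError("shape mismatch between AX and reconstruction")
    n = x.shape[0]
    diff = as_tensor(target) - h_hat
    return (diff * diff).sum() * (1.0 / (2.0 * n))


def loss_rec_a(a, a_hat_rec) -> Tensor:
    """Adjacency reconstruction (1/2N)||A − Â||_F²; A binary, self-loops excluded."""
    a = np.asarray(a.todense()) if hasattr(a, "todense") else np.asarray(a)
    a_hat_rec = as_tensor(a_hat_rec)
    if a.shape != a_hat_rec.shape:
        raise ValueError("adjacency shape mismatch")
    n = a.shape[0]
    diff = as_tensor(a.astype(np.float64)) - a_hat_rec
    return (diff * diff).sum() * (1.0 / (2.0 * n))


def _row_normalize(h: Tensor) -> Tensor:
    norms = ((h * h).sum(axis=1, keepdims=True) + _EPS) ** 0.5
    return h / norms


def cross_view_sample_corr(h1, h2) -> Tensor:
    """Node-level cross-view correlation S_N: pairwise row cosine of H1 vs H2."""
    h1n = _row_normalize(as_tensor(h1))
    h2n = _row_normalize(as_tensor(h2))
    return h1n @ h2n.T


def cross_view_feature_corr(h1, h2) -> Tensor:
    """Feature-level cross-view correlation S_F: pairwise column cosine (Z_v = H_v^T)."""
    z1 = _row_normalize(as_tensor(h1).T)
    z2 = _row_normalize(as_tensor(h2).T)
    return z1 @ z2.T


def loss_rr(s_n, s_f) -> Tensor:
    """Redundancy reduction: size-normalized MSE of S_N and S_F to identity."""
    s_n, s_f = as_tensor(s_n), as_tensor(s_f)
    n, q = s_n.shape[0], s_f.shape[0]
    dn = s_n - as_tensor(np.eye(n))
    df = s_f - as_tensor(np.eye(q))
    return (dn * dn).sum() * (1.0 / n**2) + (df * df).sum() * (1.0 / q**2)


def soft_assignment(h, centers, nu: float = 1.0) -> Tensor:
    """Student's-t soft assignment Q: q_ij ∝ (1 + ||h_i − mu_j||²/nu)^(−(nu+1)/2)."""
    h, centers = as_tensor(h), as_tensor(centers)
    sq_h = (h * h).sum(axis=1, keepdims=True)          # N x 1
    sq_c = (centers * centers).sum(axis=1, keepdims=True)  # K x 1
    d2 = sq_h + sq_c.T - (h @ centers.T) * 2.0
    # numerical floor: distances are >= 0 analytically
    kernel = (1.0 + d2 * (1.0 / nu) + _EPS) ** (-(nu + 1.0) / 2.0)
    return kernel / kernel.sum(axis=1, keepdims=True)


def target_distribution(q_soft: np.ndarray) -> np.ndarray:
    """Self-training target P: square Q, normalize by cluster frequency, renormalize rows.

    Computed on plain arrays (P is treated as a constant in the KL term).
    """
    q = np.asarray(q_soft, dtype=np.float64)
    weight = q**2 / q.sum(axis=0)
    p = weight / weight.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("target distribution undefined (empty soft cluster)")
    return p


def loss_clustering(p, q_soft) -> Tensor:
    """Clustering guidance KL(P ‖ Q) averaged over spots, with 0·log0 = 0."""
    p = np.asarray(p, dtype=np.float64)
    q_soft = as_tensor(q_soft)
    if p.shape != q_soft.shape:
        raise ValueError("P/Q shape mismatch")
    n = p.shape[0]
    logp = np.where(p > 0, np.log(np.maximum(p, _EPS)), 0.0)
    # sum p*log p is constant; only -sum p*log q carries gradient
    ent = float((p * logp).sum())
    cross = (as_tensor(p) * (q_soft + _EPS).log()).sum()
    return (as_tensor(ent) - cross) * (1.0 / n)


def total_loss(parts: dict, weights: dict | None = None) -> Tensor:
    """Weighted sum of loss terms; default unit weights give L_REC + L_C + L_RR."""
    weights = weights or {}
    total = as_tensor(0.0)
    for name, value in parts.items():
        total = total + as_tensor(value) * float(weights.get(name, 1.0))
    return total


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
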