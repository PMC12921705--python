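"""GNN survival model: GCN/GAT backbones, four graph poolings, Cox head.

A whole-slide image is summarized as a patch graph (node features = patch
embeddings, edges = spatial k-NN). Two message-passing layers and a linear
map produce 64-dim node embeddings; a pooling strategy (mean, max, gated
attention, or per-dimension Gaussian-KDE) collapses them into a single
64-dim graph embedding h; the risk score is the Cox linear predictor
``h . beta`` with no intercept (absorbed by the baseline hazard). GNN and
Cox coefficients are trained jointly by minimizing the negative Cox
partial log-likelihood over the cohort (Breslow convention for ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Parameter, Tensor, stack

NEG_INF = -1e30


class TrainingError(RuntimeError):
    """Raised when joint optimization diverges (NaN loss)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class BackboneConfig:
    arch: str = "gcn"  # {"gcn", "gat"}
    hidden_dims: Sequence[int] = (256, 128)
    embed_dim: int = 64
    gat_heads: int = 4
    dropout: float = 0.25
    pooling: str = "kde"  # {"kde", "attention", "max", "mean"}
    in_dim: int = 512
    kde_grid_size: int = 16
    kde_bandwidth: Optional[float] = None  # None -> Scott's rule per dimension
    attn_dim: int = 64

    def __post_init__(self):
        if self.arch not in ("gcn", "gat"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.pooling not in ("kde", "attention", "max", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if not self.hidden_dims:
            raise ValueError("hidden_dims must be nonempty")


@dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    seed: int = 0
    optimizer: str = "adam"


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def normalized_adjacency(n_nodes: int, edges: np.ndarray) -> np.ndarray:
    """Symmetric GCN propagation matrix D^{-1/2} (A + I) D^{-1/2} (dense)."""
    a = np.eye(n_nodes)
    if len(edges):
        a[edges[:, 0], edges[:, 1]] = 1.0
        a[edges[:, 1], edges[:, 0]] = 1.0
    dinv = 1.0 / np.sqrt(a.sum(axis=1))
    return a * dinv[:, None] * dinv[None, :]


def weighted_normalized_adjacency(n_nodes: int, edges: np.ndarray, w: Tensor) -> Tensor:
    """Differentiable D^{-1/2}(A_w + I)D^{-1/2} with per-edge weights w in (0,1]."""
    n_e = len(edges)
    both = np.concatenate([edges, edges[:, ::-1]])
    src_onehot = np.zeros((2 * n_e, n_nodes))
    dst_onehot = np.zeros((2 * n_e, n_nodes))
    src_onehot[np.arange(2 * n_e), both[:, 0]] = 1.0
    dst_onehot[np.arange(2 * n_e), both[:, 1]] = 1.0
    w2 = w[np.concatenate([np.arange(n_e), np.arange(n_e)])]
    a = Tensor(src_onehot.T) @ (Tensor(dst_onehot) * w2.reshape(-1, 1))
    a = a + Tensor(np.eye(n_nodes))
    dinv = a.sum(axis=1) ** -0.5
    return a * dinv.reshape(-1, 1) * dinv.reshape(1, -1)


class GCNLayer:
    """Kipf-Welling graph convolution: A_hat X W + b."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(_glorot(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim))

    def parameters(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor, a_hat) -> Tensor:
        a_hat = a_hat if isinstance(a_hat, Tensor) else Tensor(a_hat)
        return a_hat @ (x @ self.weight) + self.bias


class GATLayer:
    """Multi-head additive (GATv1) attention over neighbors plus self.

    `concat=True` concatenates head outputs (hidden layers); otherwise heads
    are averaged (final message-passing layer).
    """

    def __init__(self, in_dim: int, out_dim: int, heads: int,
                 rng: np.random.Generator, concat: bool = True):
        if concat and out_dim % heads:
            raise ValueError("out_dim must be divisible by heads when concatenating")
        self.heads = heads
        self.concat = concat
        dh = out_dim // heads if concat else out_dim
        self.w = [Parameter(_glorot(rng, in_dim, dh)) for _ in range(heads)]
        self.a_src = [Parameter(_glorot(rng, dh, 1, (dh,))) for _ in range(heads)]
        self.a_dst = [Parameter(_glorot(rng, dh, 1, (dh,))) for _ in range(heads)]
        self.bias = Parameter(np.zeros(out_dim))

    def parameters(self):
        return self.w + self.a_src + self.a_dst + [self.bias]

    def __call__(self, x: Tensor, adj_mask: np.ndarray,
                 extra_logits: Optional[Tensor] = None) -> Tensor:
        outs = []
        n = x.shape[0]
        for h in range(self.heads):
            z = x @ self.w[h]
            logits = (z @ self.a_src[h]).reshape(n, 1) + (z @ self.a_dst[h]).reshape(1, n)
            logits = logits.leaky_relu(0.2) + Tensor(adj_mask)
            if extra_logits is not None:
                logits = logits + extra_logits
            shift = logits.data.max(axis=1, keepdims=True)
            e = (logits - Tensor(shift)).exp()
            alpha = e / e.sum(axis=1, keepdims=True)
            outs.append(alpha @ z)
        if self.concat:
            out = outs[0]
            # concatenate along feature axis via block assembly
            blocks = []
            for h, o in enumerate(outs):
                blocks.append(o)
            out = _concat_cols(blocks)
        else:
            out = outs[0]
            for o in outs[1:]:
                out = out + o
            out = out / float(self.heads)
        return out + self.bias


def _concat_cols(tensors):
    """Column-wise concatenation of 2-D tensors."""
    dims = [t.shape[1] for t in tensors]
    total = sum(dims)
    out = None
    offset = 0
    for t, d in zip(tensors, dims):
        sel = np.zeros((d, total))
        sel[np.arange(d), offset + np.arange(d)] = 1.0
        piece = t @ Tensor(sel)
        out = piece if out is None else out + piece
        offset += d
    return out


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(_glorot(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim))

    def parameters(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


# ---------------------------------------------------------------------------
# poolings (node embeddings N x 64 -> graph embedding 64)
# ---------------------------------------------------------------------------

def pool_mean(node_embeds: Tensor) -> Tensor:
    if node_embeds.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    return node_embeds.mean(axis=0)


def pool_max(node_embeds: Tensor) -> Tensor:
    if node_embeds.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    return node_embeds.max(axis=0)


class AttentionPool:
    """Gated attention pooling: score_i = w^T tanh(V h_i), softmax weights."""

    def __init__(self, dim: int, attn_dim: int, rng: np.random.Generator):
        self.v = Parameter(_glorot(rng, attn_dim, dim, (attn_dim, dim)))
        self.w = Parameter(_glorot(rng, attn_dim, 1, (attn_dim,)))

    def parameters(self):
        return [self.v, self.w]

    def __call__(self, h: Tensor) -> Tensor:
        if h.shape[0] == 0:
            raise ValueError("cannot pool an empty graph")
        scores = (h @ self.v.T).tanh() @ self.w
        shift = scores.data.max()
        e = (scores - shift).exp()
        alpha = e / e.sum()
        return alpha @ h


class KDEPool:
    """Per-dimension gridded Gaussian-KDE pooling with a learned projection.

    For each of the 64 embedding dimensions a Gaussian KDE of the N node
    values is evaluated at `grid_size` equally spaced points spanning the
    dimension's [min, max]; the 64 x grid_size density image is flattened
    and linearly projected back to 64 dims. Grid placement and bandwidth
    are treated as constants of the current embedding (no gradient).
    """

    def __init__(self, dim: int, grid_size: int, bandwidth: Optional[float],
                 rng: np.random.Generator):
        self.dim = dim
        self.grid_size = grid_size
        self.bandwidth = bandwidth
        self.proj = Parameter(_glorot(rng, dim * grid_size, dim))

    def parameters(self):
        return [self.proj]

    def __call__(self, h: Tensor) -> Tensor:
        n = h.shape[0]
        if n == 0:
            raise ValueError("cannot pool an empty graph")
        x = h.data
        lo, hi = x.min(axis=0), x.max(axis=0)
        grid = lo[:, None] + (hi - lo)[:, None] * np.linspace(0.0, 1.0, self.grid_size)
        if self.bandwidth is not None:
            bw = np.full(self.dim, float(self.bandwidth))
        else:
            # Scott's rule per dimension, floored to stay finite on constants
            bw = x.std(axis=0) * n ** (-1.0 / 5.0)
        bw = np.maximum(bw, 1e-3)
        diff = h.reshape(n, self.dim, 1) - Tensor(grid[None, :, :])
        kern = (-(diff * diff) / (2.0 * bw[None, :, None] ** 2)).exp() \
            * (1.0 / (bw[None, :, None] * np.sqrt(2.0 * np.pi)))
        density = kern.mean(axis=0)  # dim x grid_size
        return density.reshape(self.dim * self.grid_size) @ self.proj


def kde_density_oracle(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Plain Gaussian-mixture density evaluation (reference for tests)."""
    v = values[:, None] - grid[None, :]
    return np.exp(-v**2 / (2 * bandwidth**2)).sum(axis=0) / (
        len(values) * bandwidth * np.sqrt(2 * np.pi)
    )


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def cox_partial_nll(scores, times, events):
    """Negative Cox partial log-likelihood, Breslow convention for ties.

    ``-sum_{i: event} [ s_i - log sum_{j: t_j >= t_i} exp(s_j) ]``.
    Accepts a plain array (returns float) or an autodiff Tensor (returns a
    Tensor for backprop). Events at time t are counted in their own risk set.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size < 2:
        raise ValueError("need at least two subjects")
    if not events.any():
        raise ValueError("partial likelihood undefined with no events")
    is_tensor = isinstance(scores, Tensor)
    s = scores if is_tensor else Tensor(np.asarray(scores, dtype=float))
    ev_idx = np.flatnonzero(events)
    risk = (times[None, :] >= times[ev_idx, None]).astype(float)  # n_ev x n
    c = float(s.data.max())
    lse = (Tensor(risk) @ (s - c).exp()).log() + c
    loss = -(s[ev_idx] - lse).sum()
    return loss if is_tensor else float(loss.data)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class RiskModel:
    """GNN backbone + pooling + linear Cox head emitting scalar risk scores."""

    def __init__(self, bcfg: BackboneConfig, seed: int = 0):
        self.bcfg = bcfg
        rng = np.random.default_rng(seed)
        dims = [bcfg.in_dim, *bcfg.hidden_dims]
        self.mp_layers = []
        for i in range(len(dims) - 1):
            if bcfg.arch == "gcn":
                self.mp_layers.append(GCNLayer(dims[i], dims[i + 1], rng))
            else:
                concat = i < len(dims) - 2
                self.mp_layers.append(
                    GATLayer(dims[i], dims[i + 1], bcfg.gat_heads, rng, concat=concat)
                )
        self.node_proj = Linear(dims[-1], bcfg.embed_dim, rng)
        if bcfg.pooling == "attention":
            self.pool = AttentionPool(bcfg.embed_dim, bcfg.attn_dim, rng)
        elif bcfg.pooling == "kde":
            self.pool = KDEPool(bcfg.embed_dim, bcfg.kde_grid_size, bcfg.kde_bandwidth, rng)
        else:
            self.pool = {"mean": pool_mean, "max": pool_max}[bcfg.pooling]
        self.cox_beta = Parameter(rng.normal(0.0, 0.01, bcfg.embed_dim))
        self.loss_history: list = []

    # -- parameters ----------------------------------------------------------
    def parameters(self):
        params = []
        for layer in self.mp_layers:
            params.extend(layer.parameters())
        params.extend(self.node_proj.parameters())
        if hasattr(self.pool, "parameters"):
            params.extend(self.pool.parameters())
        params.append(self.cox_beta)
        return params

    # -- forward -------------------------------------------------------------
    @staticmethod
    def _adj_mask(n_nodes: int, edges: np.ndarray) -> np.ndarray:
        mask = np.full((n_nodes, n_nodes), NEG_INF)
        np.fill_diagonal(mask, 0.0)
        if len(edges):
            mask[edges[:, 0], edges[:, 1]] = 0.0
            mask[edges[:, 1], edges[:, 0]] = 0.0
        return mask

    def embed(self, graph, edge_weights: Optional[Tensor] = None,
              node_weights: Optional[Tensor] = None,
              rng: Optional[np.random.Generator] = None, training: bool = False) -> Tensor:
        """64-dim graph embedding; edge/node weights enable explainer masking."""
        n = graph.features.shape[0]
        x = Tensor(np.asarray(graph.features, dtype=float))
        if node_weights is not None:
            x = x * node_weights.reshape(-1, 1)
        if self.bcfg.arch == "gcn":
            if edge_weights is None:
                prop = normalized_adjacency(n, graph.edges)
            else:
                prop = weighted_normalized_adjacency(n, graph.edges, edge_weights)
            for layer in self.mp_layers:
                x = layer(x, prop).relu()
                x = self._dropout(x, rng, training)
        else:
            mask = self._adj_mask(n, graph.edges)
            extra = None
            if edge_weights is not None:
                extra = _edge_logit_matrix(n, graph.edges, edge_weights)
            for i, layer in enumerate(self.mp_layers):
                x = layer(x, mask, extra).relu()
                x = self._dropout(x, rng, training)
        x = self.node_proj(x)
        return self.pool(x)

    def _dropout(self, x: Tensor, rng, training: bool) -> Tensor:
        p = self.bcfg.dropout
        if not training or p <= 0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= p).astype(float) / (1.0 - p)
        return x * Tensor(keep)

    def risk(self, graph, edge_weights: Optional[Tensor] = None,
             node_weights: Optional[Tensor] = None,
             rng=None, training: bool = False) -> Tensor:
        return self.embed(graph, edge_weights, node_weights, rng, training) @ self.cox_beta

    def risk_score(self, graph) -> float:
        """Inference-mode scalar risk for one slide graph."""
        return float(self.risk(graph).data)


def _edge_logit_matrix(n_nodes: int, edges: np.ndarray, w: Tensor) -> Tensor:
    """log(w) scattered on both edge directions (0 on the diagonal)."""
    n_e = len(edges)
    both = np.concatenate([edges, edges[:, ::-1]])
    src = np.zeros((2 * n_e, n_nodes))
    dst = np.zeros((2 * n_e, n_nodes))
    src[np.arange(2 * n_e), both[:, 0]] = 1.0
    dst[np.arange(2 * n_e), both[:, 1]] = 1.0
    logw = w[np.concatenate([np.arange(n_e), np.arange(n_e)])].log()
    return Tensor(src.T) @ (Tensor(dst) * logw.reshape(-1, 1))


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_model(model: RiskModel, path, tcfg: Optional[TrainConfig] = None):
    """Checkpoint: all weights + backbone/train configs in one archive."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    meta = {
        "backbone": {**dataclasses.asdict(model.bcfg),
                     "hidden_dims": list(model.bcfg.hidden_dims)},
        "train": dataclasses.asdict(tcfg) if tcfg else None,
        "loss_history": model.loss_history,
    }
    np.savez(path, **arrays)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> RiskModel:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    bcfg = BackboneConfig(**{k: v for k, v in meta["backbone"].items()})
    model = RiskModel(bcfg, seed=0)
    with np.load(path) as z:
        for i, p in enumerate(model.parameters()):
            p.data = z[f"param_{i}"].astype(float)
    model.loss_history = meta.get("loss_history", [])
    return model


def train_joint(graphs, records, bcfg: BackboneConfig, tcfg: TrainConfig) -> RiskModel:
    """Jointly fit GNN and Cox head by full-batch partial-likelihood descent.

    `records[i]` supplies the survival time/event inherited by `graphs[i]`
    (a patient with several slides contributes one sample per slide). Fully
    deterministic given `tcfg.seed`.
    """
    if len(graphs) != len(records):
        raise ValueError("graphs and records must align")
    if len(graphs) < 2:
        raise ValueError("need at least two samples")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if not events.any():
        raise ValueError("need at least one event to train")

    model = RiskModel(bcfg, seed=tcfg.seed)
    opt = Adam(model.parameters(), lr=tcfg.learning_rate, weight_decay=tcfg.weight_decay)
    drop_rng = np.random.default_rng((tcfg.seed * 1000003 + 17) % (2**31))
    for epoch in range(tcfg.epochs):
        scores = stack([model.risk(g, rng=drop_rng, training=True) for g in graphs])
        loss = cox_partial_nll(scores, times, events)
        if not np.isfinite(loss.data):
            raise TrainingError(
                f"non-finite loss at epoch {epoch}; history={model.loss_history[-5:]}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.loss_history.append(float(loss.data))
    return model
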