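"""Multi-head attention message passing over the G x E graph.

Node states are lifted from per-node scalar inputs via learnable
per-identity embedding/bias vectors, refined by K rounds of scaled
dot-product attention restricted to each node's in-neighborhood
(residual + layer normalization after every block, parameters tied
across rounds), and read out either by symmetric pooling over the
genotype nodes (architectures A/B) or by a learnable supernode query
attending separately over genotype and environment nodes (architecture
C).  The pooled 2d-vector feeds a small MLP regression head.

Two entry points exist on purpose: the batched, differentiable
:class:`GxEModel` used for training, and functional single-graph
operations (:func:`lift_nodes`, :func:`attention_round`, ...) that run
the same tensor code on explicit parameter containers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from .graphs import GxEGraph, SampleRecord, adjacency_mask, build_graph
from .weather import LSTMEncoder, LSTMParams

__all__ = [
    "AttentionLayerParams", "SupernodeParams", "ModelParams", "NodeStateMatrix",
    "GxEModel", "lift_nodes", "attention_round", "propagate",
    "readout_pooled", "readout_supernode", "predict_yield",
]

_NEG = -1e30  # additive mask for non-edges


@dataclass
class AttentionLayerParams:
    """Per-head projections (each d_k x d), output projection, layer-norm affine."""

    W_Q: np.ndarray                # (heads, d_k, d)
    W_K: np.ndarray
    W_V: np.ndarray
    W_O: np.ndarray                # (d, d)
    ln_gain: np.ndarray            # (d,)
    ln_bias: np.ndarray            # (d,)

    def __post_init__(self):
        h, dk, d = self.W_Q.shape
        if h * dk != d:
            raise ValueError("d must equal n_heads * d_k")
        for name in ("W_Q", "W_K", "W_V", "W_O", "ln_gain", "ln_bias"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_heads(self) -> int:
        return self.W_Q.shape[0]

    @property
    def d(self) -> int:
        return self.W_Q.shape[2]


@dataclass
class SupernodeParams:
    query: np.ndarray              # (d,)
    W_Q: np.ndarray                # (heads, d_k, d)
    W_K: np.ndarray
    W_V: np.ndarray


@dataclass
class ModelParams:
    """All learnable quantities plus the architecture configuration."""

    arch: str
    d: int
    n_heads: int
    K: int
    k_intra: int
    n_geno: int
    n_env: int
    node_embed: np.ndarray         # (n_geno + n_env, d)
    node_bias: np.ndarray          # (n_geno + n_env, d)
    attention: AttentionLayerParams
    mlp: list                      # [(W, b), ...] with W: (fan_in, fan_out)
    supernode: SupernodeParams | None = None
    lstm: LSTMParams | None = None

    def __post_init__(self):
        if self.d % self.n_heads != 0:
            raise ValueError("d must be divisible by n_heads")
        if self.mlp and self.mlp[0][0].shape[0] != 2 * self.d:
            raise ValueError("MLP input dimension must equal 2d")
        if self.arch == "C" and self.supernode is None:
            raise ValueError("architecture C requires supernode parameters")


@dataclass
class NodeStateMatrix:
    H: np.ndarray                  # (n + m, d)
    n_geno: int
    n_env: int
    round_index: int = 0

    @property
    def H_g(self) -> np.ndarray:
        return self.H[: self.n_geno]

    @property
    def H_e(self) -> np.ndarray:
        return self.H[self.n_geno:]


# ---------------------------------------------------------------------------
# shared tensor kernels (batched; functional ops call these with B=1)
# ---------------------------------------------------------------------------

def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


def _split_heads(x: Tensor, n_heads: int, d_k: int) -> Tensor:
    """(B, N, h*d_k) -> (B, h, N, d_k)."""
    B, N, _ = x.shape
    return x.reshape(B, N, n_heads, d_k).swapaxes(1, 2)


def _attention_round_t(
    H: Tensor,
    mask: np.ndarray,              # (B, N, N) bool, mask[i, j]: edge j -> i
    Wq: Tensor, Wk: Tensor, Wv: Tensor, Wo: Tensor,
    ln_gain: Tensor, ln_bias: Tensor,
    n_heads: int,
) -> Tensor:
    B, N, d = H.shape
    d_k = d // n_heads
    Q = _split_heads(H @ Wq.T, n_heads, d_k)
    K = _split_heads(H @ Wk.T, n_heads, d_k)
    V = _split_heads(H @ Wv.T, n_heads, d_k)
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    bias = np.where(mask, 0.0, _NEG)[:, None, :, :]
    att = (scores + Tensor(bias)).softmax(axis=-1)          # (B, h, N, N)
    if not np.isfinite(att.data).all():
        bad = np.argwhere(~np.isfinite(att.data))[0]
        raise FloatingPointError(f"non-finite attention score at node {int(bad[2])}")
    msg = (att @ V).swapaxes(1, 2).reshape(B, N, d) @ Wo.T
    has_nbr = mask.any(axis=2).astype(np.float64)[:, :, None]
    msg = msg * Tensor(has_nbr)                             # isolated nodes: no message
    return _layer_norm(H + msg, ln_gain, ln_bias)


def _supernode_readout_t(
    Hset: Tensor,                  # (B, n_set, d)
    query: Tensor, Wq: Tensor, Wk: Tensor, Wv: Tensor,
    n_heads: int,
) -> tuple[Tensor, Tensor]:
    """Returns (z: (B, d), attention weights: (B, h, n_set))."""
    B, n_set, d = Hset.shape
    d_k = d // n_heads
    q = (Wq @ query).reshape(n_heads, d_k)                  # per-head query
    K = _split_heads(Hset @ Wk.T, n_heads, d_k)             # (B, h, n, d_k)
    V = _split_heads(Hset @ Wv.T, n_heads, d_k)
    scores = (K * q.reshape(1, n_heads, 1, d_k)).sum(axis=-1) * (1.0 / np.sqrt(d_k))
    att = scores.softmax(axis=-1)                           # (B, h, n)
    z = (att.reshape(B, n_heads, n_set, 1) * V).sum(axis=2) # (B, h, d_k)
    return z.reshape(B, d), att


def _pooled_readout_t(Hg: Tensor) -> Tensor:
    """concat(mean, max) over genotype rows: (B, n, d) -> (B, 2d)."""
    return concat([Hg.mean(axis=1), Hg.max(axis=1)], axis=-1)


def _mlp_t(x: Tensor, layers: list[tuple[Tensor, Tensor]]) -> Tensor:
    h = x
    for i, (W, b) in enumerate(layers):
        h = h @ W + b
        if i < len(layers) - 1:
            h = h.relu()
    return h


# ---------------------------------------------------------------------------
# trainable model
# ---------------------------------------------------------------------------

class GxEModel:
    """Batched differentiable model: lift -> K attention rounds -> readout -> MLP."""

    def __init__(
        self,
        arch: str,
        n_geno: int,
        n_env: int,
        d: int = 128,
        n_heads: int = 8,
        K: int = 30,
        k_intra: int = 10,
        head_dims: tuple[int, int] = (128, 64),
        lstm_m: int | None = None,
        seed: int = 0,
    ):
        if arch not in ("A", "B", "C"):
            raise ValueError(f"unknown architecture {arch!r}")
        if d % n_heads != 0:
            raise ValueError("d must be divisible by n_heads")
        self.arch = arch
        self.n_geno, self.n_env = n_geno, n_env
        self.d, self.n_heads, self.K, self.k_intra = d, n_heads, K, k_intra
        rng = np.random.default_rng(seed)
        N = n_geno + n_env
        s = 0.1
        self.node_embed = Tensor(rng.normal(0, s, (N, d)), requires_grad=True)
        self.node_bias = Tensor(rng.normal(0, s, (N, d)), requires_grad=True)
        proj = lambda: Tensor(rng.normal(0, 1 / np.sqrt(d), (d, d)), requires_grad=True)
        self.Wq, self.Wk, self.Wv, self.Wo = proj(), proj(), proj(), proj()
        self.ln_gain = Tensor(np.ones(d), requires_grad=True)
        self.ln_bias = Tensor(np.zeros(d), requires_grad=True)
        if arch == "C":
            self.s_query = Tensor(rng.normal(0, 1, d), requires_grad=True)
            self.Wq_s, self.Wk_s, self.Wv_s = proj(), proj(), proj()
        dims = [2 * d, *head_dims, 1]
        self.mlp: list[tuple[Tensor, Tensor]] = []
        for i, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
            W = Tensor(rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)),
                       requires_grad=True)
            # small positive bias keeps hidden rectifier units initially alive
            b0 = 0.01 if i < len(dims) - 2 else 0.0
            b = Tensor(np.full(fan_out, b0), requires_grad=True)
            self.mlp.append((W, b))
        self.out_bias = Tensor(np.zeros(1), requires_grad=True)
        self.lstm: LSTMEncoder | None = None
        if lstm_m is not None:
            if lstm_m != n_env:
                raise ValueError("lstm_m must equal the environment node count")
            self.lstm = LSTMEncoder.init(lstm_m, seed + 1)

    # -- parameter plumbing --------------------------------------------------

    def parameters(self) -> list[Tensor]:
        ps = [self.node_embed, self.node_bias, self.Wq, self.Wk, self.Wv, self.Wo,
              self.ln_gain, self.ln_bias, self.out_bias]
        if self.arch == "C":
            ps += [self.s_query, self.Wq_s, self.Wk_s, self.Wv_s]
        for W, b in self.mlp:
            ps += [W, b]
        if self.lstm is not None:
            ps += self.lstm.parameters()
        return ps

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    # -- forward -------------------------------------------------------------

    def lift(self, values: Tensor) -> Tensor:
        """(B, N) scalar node inputs -> (B, N, d) initial states."""
        B, N = values.shape
        return values.reshape(B, N, 1) * self.node_embed + self.node_bias

    def propagate(self, H: Tensor, mask: np.ndarray) -> Tensor:
        for _ in range(self.K):
            H = _attention_round_t(H, mask, self.Wq, self.Wk, self.Wv, self.Wo,
                                   self.ln_gain, self.ln_bias, self.n_heads)
        return H

    def readout(self, H: Tensor) -> Tensor:
        n = self.n_geno
        B, N, d = H.shape
        Hg = H[:, :n, :]
        if self.arch in ("A", "B"):
            return _pooled_readout_t(Hg)
        He = H[:, n:, :]
        zg, _ = _supernode_readout_t(Hg, self.s_query, self.Wq_s, self.Wk_s,
                                     self.Wv_s, self.n_heads)
        ze, _ = _supernode_readout_t(He, self.s_query, self.Wq_s, self.Wk_s,
                                     self.Wv_s, self.n_heads)
        return concat([zg, ze], axis=-1)

    def forward_values(self, values: Tensor, mask: np.ndarray) -> Tensor:
        """values (B, N) -> predicted yields (B,)."""
        H = self.lift(values)
        H = self.propagate(H, mask)
        z = self.readout(H)
        return (_mlp_t(z, self.mlp) + self.out_bias)[:, 0]

    def build_masks(self, values: np.ndarray) -> np.ndarray:
        """Adjacency masks (B, N, N) for a batch of node-value rows."""
        from .graphs import batch_intra_masks, bipartite_mask

        B, N = values.shape
        n, m = self.n_geno, self.n_env
        base = bipartite_mask(n, m)
        masks = np.broadcast_to(base, (B, N, N)).copy()
        if self.arch in ("B", "C"):
            masks[:, :n, :n] = batch_intra_masks(values[:, :n], self.k_intra)
            masks[:, n:, n:] = batch_intra_masks(values[:, n:], self.k_intra)
        return masks

    # -- conversion to/from explicit parameter containers ---------------------

    def to_params(self) -> ModelParams:
        d, h = self.d, self.n_heads
        dk = d // h
        layer = AttentionLayerParams(
            W_Q=self.Wq.data.reshape(h, dk, d).copy(),
            W_K=self.Wk.data.reshape(h, dk, d).copy(),
            W_V=self.Wv.data.reshape(h, dk, d).copy(),
            W_O=self.Wo.data.copy(),
            ln_gain=self.ln_gain.data.copy(),
            ln_bias=self.ln_bias.data.copy(),
        )
        sn = None
        if self.arch == "C":
            sn = SupernodeParams(
                query=self.s_query.data.copy(),
                W_Q=self.Wq_s.data.reshape(h, dk, d).copy(),
                W_K=self.Wk_s.data.reshape(h, dk, d).copy(),
                W_V=self.Wv_s.data.reshape(h, dk, d).copy(),
            )
        mlp = [(W.data.copy(), b.data.copy()) for W, b in self.mlp]
        mlp[-1] = (mlp[-1][0], mlp[-1][1] + self.out_bias.data)
        return ModelParams(
            arch=self.arch, d=d, n_heads=h, K=self.K, k_intra=self.k_intra,
            n_geno=self.n_geno, n_env=self.n_env,
            node_embed=self.node_embed.data.copy(),
            node_bias=self.node_bias.data.copy(),
            attention=layer, mlp=mlp, supernode=sn,
            lstm=self.lstm.to_params() if self.lstm is not None else None,
        )

    @classmethod
    def from_params(cls, params: ModelParams) -> "GxEModel":
        hd = tuple(W.shape[1] for W, _ in params.mlp[:-1])
        model = cls(params.arch, params.n_geno, params.n_env, d=params.d,
                    n_heads=params.n_heads, K=params.K, k_intra=params.k_intra,
                    head_dims=hd, lstm_m=params.lstm.m if params.lstm else None)
        h, d = params.n_heads, params.d
        model.Wq.data = params.attention.W_Q.reshape(d, d).copy()
        model.Wk.data = params.attention.W_K.reshape(d, d).copy()
        model.Wv.data = params.attention.W_V.reshape(d, d).copy()
        model.Wo.data = params.attention.W_O.copy()
        model.ln_gain.data = params.attention.ln_gain.copy()
        model.ln_bias.data = params.attention.ln_bias.copy()
        model.node_embed.data = params.node_embed.copy()
        model.node_bias.data = params.node_bias.copy()
        if params.arch == "C":
            model.s_query.data = params.supernode.query.copy()
            model.Wq_s.data = params.supernode.W_Q.reshape(d, d).copy()
            model.Wk_s.data = params.supernode.W_K.reshape(d, d).copy()
            model.Wv_s.data = params.supernode.W_V.reshape(d, d).copy()
        for (W, b), (Wn, bn) in zip(model.mlp, params.mlp):
            W.data = Wn.copy()
            b.data = bn.copy()
        model.out_bias.data = np.zeros(1)
        if params.lstm is not None:
            model.lstm = LSTMEncoder(params.lstm)
        return model


# ---------------------------------------------------------------------------
# functional single-graph operations
# ---------------------------------------------------------------------------

def _layer_tensors(layer: AttentionLayerParams):
    h, dk, d = layer.W_Q.shape
    return (Tensor(layer.W_Q.reshape(d, d)), Tensor(layer.W_K.reshape(d, d)),
            Tensor(layer.W_V.reshape(d, d)), Tensor(layer.W_O),
            Tensor(layer.ln_gain), Tensor(layer.ln_bias))


def lift_nodes(graph: GxEGraph, params: ModelParams) -> NodeStateMatrix:
    """h_i(0) = value_i * embed_i + bias_i."""
    N = graph.n_nodes
    if params.node_embed.shape[0] != N:
        raise ValueError(f"graph has {N} nodes but params expect "
                         f"{params.node_embed.shape[0]}")
    H = graph.node_values[:, None] * params.node_embed + params.node_bias
    return NodeStateMatrix(H=H, n_geno=graph.n_geno_nodes, n_env=graph.n_env_nodes)


def attention_round(
    H: NodeStateMatrix, graph: GxEGraph, layer: AttentionLayerParams
) -> NodeStateMatrix:
    """One masked multi-head attention block with residual + layer norm."""
    if not np.isfinite(H.H).all():
        raise ValueError("non-finite node states")
    mask = adjacency_mask(graph)[None]
    out = _attention_round_t(Tensor(H.H[None]), mask, *_layer_tensors(layer),
                             n_heads=layer.n_heads)
    return NodeStateMatrix(H=out.data[0], n_geno=H.n_geno, n_env=H.n_env,
                           round_index=H.round_index + 1)


def propagate(H0: NodeStateMatrix, graph: GxEGraph, params: ModelParams) -> NodeStateMatrix:
    if params.K < 1:
        raise ValueError("K must be >= 1")
    H = H0
    for _ in range(params.K):
        H = attention_round(H, graph, params.attention)
    return H


def readout_pooled(H: NodeStateMatrix) -> np.ndarray:
    """concat(mean, max) over genotype rows -> 2d-vector."""
    if H.n_geno < 1:
        raise ValueError("need at least one genotype node")
    return np.concatenate([H.H_g.mean(axis=0), H.H_g.max(axis=0)])


def readout_supernode(H: NodeStateMatrix, params: ModelParams) -> np.ndarray:
    """Supernode attention over genotype and environment nodes -> [z_g; z_e]."""
    sn = params.supernode
    if sn is None:
        raise ValueError("supernode parameters missing")
    d = params.d
    q, Wq = Tensor(sn.query), Tensor(sn.W_Q.reshape(d, d))
    Wk, Wv = Tensor(sn.W_K.reshape(d, d)), Tensor(sn.W_V.reshape(d, d))
    zg, _ = _supernode_readout_t(Tensor(H.H_g[None]), q, Wq, Wk, Wv, params.n_heads)
    ze, _ = _supernode_readout_t(Tensor(H.H_e[None]), q, Wq, Wk, Wv, params.n_heads)
    return np.concatenate([zg.data[0], ze.data[0]])


def supernode_attention_weights(H: NodeStateMatrix, params: ModelParams) -> np.ndarray:
    """Per-head attention weights over the genotype nodes, (heads, n)."""
    sn = params.supernode
    d = params.d
    q, Wq = Tensor(sn.query), Tensor(sn.W_Q.reshape(d, d))
    Wk, Wv = Tensor(sn.W_K.reshape(d, d)), Tensor(sn.W_V.reshape(d, d))
    _, att = _supernode_readout_t(Tensor(H.H_g[None]), q, Wq, Wk, Wv, params.n_heads)
    return att.data[0]


def predict_yield(sample: SampleRecord, params: ModelParams, arch: str | None = None) -> float:
    """Full forward pass for one sample; deterministic."""
    arch = arch or params.arch
    graph = build_graph(sample, arch, k=params.k_intra if arch in ("B", "C") else None)
    H = propagate(lift_nodes(graph, params), graph, params)
    z = readout_pooled(H) if arch in ("A", "B") else readout_supernode(H, params)
    out = Tensor(z[None])
    pred = _mlp_t(out, [(Tensor(W), Tensor(b)) for W, b in params.mlp])
    return float(pred.data[0, 0])
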