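"""Per-sample G x E graph construction.

Each (hybrid, environment) sample yields a graph whose first ``n`` nodes
carry that hybrid's principal-component scores and whose last ``m``
nodes carry the environment embedding components.  Architecture A keeps
only the fully connected bipartite blocks (both directions); B and C add
directed intra-set top-k similarity edges with fixed out-degree k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GxEGraph", "SampleRecord", "similarity", "topk_intra_edges",
           "build_graph", "adjacency_mask", "intra_mask", "bipartite_mask"]

ARCHITECTURES = ("A", "B", "C")

BLOCKS = ("GG", "GE", "EG", "EE")


@dataclass
class SampleRecord:
    hybrid_id: str
    env_id: str
    year: int
    genotype_scores: np.ndarray    # (n,)
    env_embedding: np.ndarray      # (m,)
    yield_mg_ha: float | None = None

    def __post_init__(self):
        self.genotype_scores = np.asarray(self.genotype_scores, dtype=np.float64)
        self.env_embedding = np.asarray(self.env_embedding, dtype=np.float64)
        if self.genotype_scores.ndim != 1 or self.env_embedding.ndim != 1:
            raise ValueError("sample feature vectors must be 1-D")


@dataclass
class GxEGraph:
    n_geno_nodes: int
    n_env_nodes: int
    node_values: np.ndarray        # (n + m,): PC scores then z_env components
    edges: dict = field(default_factory=dict)  # block -> list[(src, dst)]

    def __post_init__(self):
        n, m = self.n_geno_nodes, self.n_env_nodes
        if self.node_values.shape != (n + m,):
            raise ValueError("node_values length must be n + m")
        for block in BLOCKS:
            self.edges.setdefault(block, [])
        for u, v in self.all_edges():
            if u == v:
                raise ValueError("self-loops are not allowed")

    def all_edges(self) -> list[tuple[int, int]]:
        return [e for block in BLOCKS for e in self.edges[block]]

    @property
    def n_nodes(self) -> int:
        return self.n_geno_nodes + self.n_env_nodes


def similarity(x_u: np.ndarray, x_v: np.ndarray) -> float:
    """1 / (1 + ||x_u - x_v||); absolute difference for scalars."""
    x_u = np.atleast_1d(np.asarray(x_u, dtype=np.float64))
    x_v = np.atleast_1d(np.asarray(x_v, dtype=np.float64))
    if x_u.shape != x_v.shape:
        raise ValueError("similarity requires equal-length vectors")
    if not (np.isfinite(x_u).all() and np.isfinite(x_v).all()):
        raise ValueError("similarity requires finite inputs")
    return float(1.0 / (1.0 + np.linalg.norm(x_u - x_v)))


def topk_intra_edges(values: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Directed edges u -> v to each node's k most similar peers.

    Ties break toward the lower node index; k is capped at set size - 1.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.shape[0]
    if n < 1:
        raise ValueError("need at least one node")
    if k < 0:
        raise ValueError("k must be >= 0")
    k = min(k, n - 1)
    if k == 0:
        return []
    # similarity is monotone-decreasing in |value difference|, so rank by distance
    dist = np.abs(values[:, None] - values[None, :])
    edges = []
    for u in range(n):
        order = sorted((v for v in range(n) if v != u), key=lambda v: (dist[u, v], v))
        edges.extend((u, v) for v in order[:k])
    return edges


def build_graph(sample: SampleRecord, arch: str, k: int | None = None) -> GxEGraph:
    """Assemble the block graph for one sample under architecture A, B or C."""
    if arch not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {arch!r}; expected one of {ARCHITECTURES}")
    n = sample.genotype_scores.shape[0]
    m = sample.env_embedding.shape[0]
    node_values = np.concatenate([sample.genotype_scores, sample.env_embedding])
    edges: dict[str, list[tuple[int, int]]] = {b: [] for b in BLOCKS}
    edges["GE"] = [(g, n + e) for g in range(n) for e in range(m)]
    edges["EG"] = [(n + e, g) for e in range(m) for g in range(n)]
    if arch in ("B", "C"):
        if k is None:
            raise ValueError("architectures B and C require k")
        edges["GG"] = topk_intra_edges(sample.genotype_scores, k)
        edges["EE"] = [(n + u, n + v) for u, v in topk_intra_edges(sample.env_embedding, k)]
    return GxEGraph(n_geno_nodes=n, n_env_nodes=m, node_values=node_values, edges=edges)


# ---------------------------------------------------------------------------
# dense masks consumed by the attention network
# ---------------------------------------------------------------------------

def adjacency_mask(graph: GxEGraph) -> np.ndarray:
    """Boolean (N, N) with mask[i, j] = True iff edge j -> i exists."""
    N = graph.n_nodes
    mask = np.zeros((N, N), dtype=bool)
    for u, v in graph.all_edges():
        mask[v, u] = True
    return mask


def bipartite_mask(n: int, m: int) -> np.ndarray:
    """In-neighbor mask of the fully connected bipartite blocks."""
    mask = np.zeros((n + m, n + m), dtype=bool)
    mask[:n, n:] = True
    mask[n:, :n] = True
    return mask


def intra_mask(values: np.ndarray, k: int) -> np.ndarray:
    """In-neighbor mask of the top-k intra-set edges over one node set."""
    n = values.shape[0]
    mask = np.zeros((n, n), dtype=bool)
    for u, v in topk_intra_edges(values, k):
        mask[v, u] = True
    return mask


def batch_intra_masks(values: np.ndarray, k: int) -> np.ndarray:
    """Vectorized intra masks for a batch: values (B, n) -> bool (B, n, n).

    Same tie rule as :func:`topk_intra_edges` (distance, then lower index).
    """
    B, n = values.shape
    k = min(k, n - 1)
    masks = np.zeros((B, n, n), dtype=bool)
    if k == 0:
        return masks
    dist = np.abs(values[:, :, None] - values[:, None, :])
    idx = np.broadcast_to(np.arange(n), (B, n, n))
    dist = dist + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    order = np.lexsort((idx, dist), axis=2)[:, :, :k]  # neighbors of u per row
    b_ix = np.repeat(np.arange(B), n * k)
    u_ix = np.tile(np.repeat(np.arange(n), k), B)
    v_ix = order.reshape(-1)
    masks[b_ix, v_ix.astype(int), u_ix] = True  # edge u -> v: in-mask[v, u]
    return masks
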