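"""Graph multihead attention pooling.

A pooling layer owns a learnable seed-query matrix Q with one row per
output cluster.  Keys and values are produced by dedicated GCNs over the
current graph, so the attention weights reflect both node features and
structure.  The head-averaged attention weights, transposed, are the soft
assignment matrix S (n x nc, each cluster's column summing to 1 over real
nodes); cluster embeddings come from the transformer-style block
LN(Z + FFN(Z)) with Z = LN(Q + MultiHead(Q, K, V)), and the coarsened
adjacency is S^T A S.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, glorot_uniform, layer_norm, masked_softmax
from .gcn import GCNLayer

__all__ = [
    "scaled_dot_attention",
    "compute_assignment",
    "coarsen_adjacency",
    "GMAPool",
]


def scaled_dot_attention(
    q: Tensor | np.ndarray,
    k: Tensor | np.ndarray,
    v: Tensor | np.ndarray,
    key_mask: np.ndarray | None = None,
    scale: float | None = None,
) -> tuple[Tensor, Tensor]:
    """softmax(Q K^T / scale) V with optional key masking.

    Returns ``(output, weights)``; each weights row sums to 1 over
    unmasked keys and is exactly 0 at masked keys.  `scale` defaults to
    sqrt of the key dimension.
    """
    q, k, v = Tensor._lift(q), Tensor._lift(k), Tensor._lift(v)
    if scale is None:
        scale = float(np.sqrt(k.shape[1]))
    logits = (q @ k.T) * (1.0 / scale)
    if key_mask is None:
        key_mask = np.ones(k.shape[0], dtype=bool)
    key_mask = np.asarray(key_mask, dtype=bool)
    if not key_mask.any():
        raise ValueError("attention requires at least one unmasked key")
    weights = masked_softmax(logits, key_mask[None, :], axis=-1)
    return weights @ v, weights


def compute_assignment(head_weights: list[Tensor], mask: np.ndarray | None = None) -> Tensor:
    """Average per-head attention weights (nc x n each) and transpose to S (n x nc).

    Rows of each head's weights sum to 1 over real nodes, so every column
    of S sums to 1; rows at masked (padded) node positions are exactly 0
    because masked attention weights are exactly 0.
    """
    avg = head_weights[0]
    for w in head_weights[1:]:
        avg = avg + w
    return (avg * (1.0 / len(head_weights))).T


def coarsen_adjacency(s: Tensor | np.ndarray, a: Tensor | np.ndarray):
    """Coarsened adjacency S^T A S; numpy in, numpy out."""
    if isinstance(s, Tensor) or isinstance(a, Tensor):
        s_t, a_t = Tensor._lift(s), Tensor._lift(a)
        if s_t.shape[0] != a_t.shape[0] or a_t.shape[0] != a_t.shape[1]:
            raise ValueError(f"shape mismatch: S {s_t.shape}, A {a_t.shape}")
        return s_t.T @ a_t @ s_t
    s_np, a_np = np.asarray(s, dtype=np.float64), np.asarray(a, dtype=np.float64)
    if s_np.shape[0] != a_np.shape[0] or a_np.shape[0] != a_np.shape[1]:
        raise ValueError(f"shape mismatch: S {s_np.shape}, A {a_np.shape}")
    return s_np.T @ a_np @ s_np


class GMAPool:
    """One multihead-attention pooling layer: n nodes -> nc clusters.

    Parameters
    ----------
    d : hidden dimension (divisible by the head count).
    nc : number of output clusters; fixed by the learnable seed matrix.
    heads : number of attention heads; each works in a d/heads subspace
        with softmax scale sqrt(d/heads).
    d_ff : inner width of the position-wise feed-forward block (default 2d).
    """

    def __init__(self, d: int, nc: int, heads: int, rng: np.random.Generator, d_ff: int | None = None):
        if nc < 1:
            raise ValueError("nc must be >= 1")
        if d % heads != 0:
            raise ValueError(f"hidden dim {d} not divisible by head count {heads}")
        self.d = d
        self.nc = nc
        self.heads = heads
        self.d_head = d // heads
        d_ff = 2 * d if d_ff is None else d_ff

        self.seed_queries = glorot_uniform((nc, d), rng)
        self.w_q = [glorot_uniform((d, self.d_head), rng) for _ in range(heads)]
        self.w_k = [glorot_uniform((d, self.d_head), rng) for _ in range(heads)]
        self.w_v = [glorot_uniform((d, self.d_head), rng) for _ in range(heads)]
        self.w_o = glorot_uniform((d, d), rng)
        self.key_gnn = GCNLayer(d, d, rng, relu=True)
        self.value_gnn = GCNLayer(d, d, rng, relu=True)
        self.ffn_w1 = glorot_uniform((d, d_ff), rng)
        self.ffn_b1 = Tensor(np.zeros(d_ff), requires_grad=True)
        self.ffn_w2 = glorot_uniform((d_ff, d), rng)
        self.ffn_b2 = Tensor(np.zeros(d), requires_grad=True)
        self.ln1_g = Tensor(np.ones(d), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(d), requires_grad=True)
        self.ln2_g = Tensor(np.ones(d), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(d), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return (
            [self.seed_queries]
            + self.w_q + self.w_k + self.w_v
            + [self.w_o]
            + self.key_gnn.parameters()
            + self.value_gnn.parameters()
            + [self.ffn_w1, self.ffn_b1, self.ffn_w2, self.ffn_b2,
               self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b]
        )

    # -- attention stack ----------------------------------------------

    def multihead_attention(
        self, q: Tensor, k: Tensor, v: Tensor, key_mask: np.ndarray | None = None
    ) -> tuple[Tensor, list[Tensor]]:
        """Per-head projected attention, concatenated and reprojected.

        Returns the nc x d output and the list of per-head weight
        matrices (each nc x n).
        """
        outs, weights = [], []
        scale = float(np.sqrt(self.d_head))
        for i in range(self.heads):
            o, w = scaled_dot_attention(q @ self.w_q[i], k @ self.w_k[i], v @ self.w_v[i],
                                        key_mask=key_mask, scale=scale)
            outs.append(o)
            weights.append(w)
        return concat(outs, axis=1) @ self.w_o, weights

    def gma(self, h: Tensor, a_norm, key_mask: np.ndarray | None = None) -> tuple[Tensor, list[Tensor]]:
        """Multihead attention with GCN-generated keys and values."""
        keys = self.key_gnn(h, a_norm)
        values = self.value_gnn(h, a_norm)
        return self.multihead_attention(self.seed_queries, keys, values, key_mask=key_mask)

    def forward(self, h: Tensor, a_norm, key_mask: np.ndarray | None = None) -> tuple[Tensor, Tensor, list[Tensor]]:
        """Full pooling block.

        Returns ``(cluster_embeddings nc x d, S n x nc, per-head weights)``.
        """
        attended, head_weights = self.gma(h, a_norm, key_mask=key_mask)
        z = layer_norm(self.seed_queries + attended, self.ln1_g, self.ln1_b)
        ffn = ((z @ self.ffn_w1 + self.ffn_b1).relu()) @ self.ffn_w2 + self.ffn_b2
        out = layer_norm(z + ffn, self.ln2_g, self.ln2_b)
        s = compute_assignment(head_weights, key_mask)
        return out, s, head_weights
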