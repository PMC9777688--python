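"""Self-supervised mutual-information maximization over coarsened graphs.

After each pooling layer, a sigmoid readout summarizes the cluster
embeddings into a graph-level vector r; a bilinear discriminator scores
how likely an embedding row belongs to the graph summarized by r.  The
training signal is a noise-contrastive binary cross-entropy: the graph's
own cluster embeddings are positives, another in-batch graph's cluster
embeddings are negatives.  Maximizing this discriminability is a proxy
for maximizing mutual information between cluster and graph-level
representations.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, glorot_uniform

__all__ = ["MIModule", "readout_global", "discriminate", "mi_loss", "corrupt_batch"]

_CLAMP = 1e-7  # probability floor/ceiling for the log terms


def readout_global(h: Tensor | np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Sigmoid of the mean over real node rows: entries strictly in (0, 1)."""
    h = Tensor._lift(h)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("readout requires at least one real node")
        h = h[mask]
    elif h.shape[0] < 1:
        raise ValueError("readout requires at least one row")
    return h.mean(axis=0).sigmoid()


class MIModule:
    """Bilinear discriminator D(h, r) = sigmoid(h^T W_D r) plus loss weight."""

    def __init__(self, d: int, rng: np.random.Generator, weight: float = 1.0):
        if weight < 0:
            raise ValueError("loss weight must be nonnegative")
        self.w_d = glorot_uniform((d, d), rng)
        self.weight = weight

    def parameters(self) -> list[Tensor]:
        return [self.w_d]


def discriminate(module: MIModule, h: Tensor | np.ndarray, r: Tensor | np.ndarray) -> Tensor:
    """Per-row probability scores sigmoid(H W_D r), shape (n,)."""
    h, r = Tensor._lift(h), Tensor._lift(r)
    return (h @ module.w_d @ r.reshape(-1, 1)).reshape(-1).sigmoid()


def mi_loss(module: MIModule, h_pos: Tensor | np.ndarray, h_neg: Tensor | np.ndarray,
            r: Tensor | np.ndarray) -> Tensor:
    """Noise-contrastive BCE against the summary vector r.

    L = -(1/(n_pos+n_neg)) [sum log D(pos, r) + sum log(1 - D(neg, r))],
    with scores clamped away from {0, 1} for numerical safety.  L >= 0,
    and equals ln 2 when every score is exactly 0.5.
    """
    h_pos, h_neg = Tensor._lift(h_pos), Tensor._lift(h_neg)
    if h_pos.shape[0] < 1 or h_neg.shape[0] < 1:
        raise ValueError("need at least one positive and one negative sample")
    d_pos = discriminate(module, h_pos, r).clamp(_CLAMP, 1.0 - _CLAMP)
    d_neg = discriminate(module, h_neg, r).clamp(_CLAMP, 1.0 - _CLAMP)
    total = d_pos.log().sum() + (1.0 - d_neg).log().sum()
    return -total * (1.0 / (h_pos.shape[0] + h_neg.shape[0]))


def corrupt_batch(embeddings: list[Tensor], rng: np.random.Generator) -> list[Tensor]:
    """Negative samples: graph b gets graph (b+1 mod B)'s cluster embeddings.

    A single-graph batch falls back to a seeded row permutation of the
    graph's own embeddings.  Gradients flow through the negatives, as
    they are live embeddings from the same forward pass.
    """
    B = len(embeddings)
    if B < 1:
        raise ValueError("empty batch")
    if B == 1:
        e = embeddings[0]
        perm = rng.permutation(e.shape[0])
        return [e[perm]]
    return [embeddings[(b + 1) % B] for b in range(B)]
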