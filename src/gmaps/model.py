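"""Hierarchical GNN: conv -> pool -> conv -> pool -> conv, JK readout, MLP.

The stack alternates three GCN layers with two attention pooling layers.
Cluster counts shrink geometrically with the pooling ratio r relative to
a reference node count (the training set's maximum), because the seed
queries fix each pooling layer's output size.  Graph-level features are
the concatenated masked means of the three conv layers' outputs (jumping
knowledge), classified by a three-layer MLP with dropout and a softmax.
When MI is enabled, a contrastive loss is computed after each pooling
layer and added to the cross-entropy with weight lambda.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam, Tensor, concat, dropout, glorot_uniform, softmax
from .gcn import GCNLayer, normalize_adjacency, normalize_adjacency_t
from .graph_data import DenseBatch
from .mi import MIModule, corrupt_batch, mi_loss, readout_global
from .pool import GMAPool, coarsen_adjacency

__all__ = ["ModelConfig", "HierarchicalGNN", "ForwardResult", "cross_entropy", "total_loss"]

_CLAMP = 1e-7


@dataclass
class ModelConfig:
    """Hyperparameters of the hierarchical classifier.

    Defaults follow the reference protocol: hidden size 128, 25% pooling
    ratio, 50% dropout, MLP hidden sizes 128 and 56.
    """

    feature_dim: int = 1
    num_classes: int = 2
    hidden: int = 128
    heads: int = 4
    pool_ratio: float = 0.25
    mi_weight: float = 1.0
    use_mi: bool = True
    dropout: float = 0.5
    mlp_hidden: tuple[int, int] = (128, 56)
    ref_nodes: int = 32          # training-set max node count; sets nc1
    nc_from_original: bool = False  # nc2 from ref_nodes instead of nc1
    d_ff: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden % self.heads != 0:
            raise ValueError("hidden must be divisible by heads")
        if not (0.0 < self.pool_ratio <= 1.0):
            raise ValueError("pool_ratio must be in (0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def nc1(self) -> int:
        return max(1, math.ceil(self.pool_ratio * self.ref_nodes))

    @property
    def nc2(self) -> int:
        base = self.ref_nodes * self.pool_ratio if self.nc_from_original else self.nc1
        return max(1, math.ceil(self.pool_ratio * base)) if self.nc_from_original else max(
            1, math.ceil(self.pool_ratio * self.nc1))


@dataclass
class ForwardResult:
    """Everything a forward pass produces, per batch."""

    probs: Tensor                       # (B, C), rows sum to 1
    mi_losses: list[Tensor]             # one per pooling layer (empty if MI off)
    assignments: list[list[Tensor]]     # per graph: [S1 (n x nc1), S2 (nc1 x nc2)]
    states: list[list[Tensor]]          # per graph: conv outputs [h1, h2, h3]
    jk: Tensor                          # (B, 3d) graph-level features


class HierarchicalGNN:
    """Three conv layers, two attention pooling layers, MLP classifier."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.hidden
        self.conv1 = GCNLayer(config.feature_dim, d, rng)
        self.pool1 = GMAPool(d, config.nc1, config.heads, rng, d_ff=config.d_ff)
        self.conv2 = GCNLayer(d, d, rng)
        self.pool2 = GMAPool(d, config.nc2, config.heads, rng, d_ff=config.d_ff)
        self.conv3 = GCNLayer(d, d, rng)
        self.mi1 = MIModule(d, rng, config.mi_weight)
        self.mi2 = MIModule(d, rng, config.mi_weight)
        h1, h2 = config.mlp_hidden
        self.mlp_w1 = glorot_uniform((3 * d, h1), rng)
        self.mlp_b1 = Tensor(np.zeros(h1), requires_grad=True)
        self.mlp_w2 = glorot_uniform((h1, h2), rng)
        self.mlp_b2 = Tensor(np.zeros(h2), requires_grad=True)
        self.mlp_w3 = glorot_uniform((h2, config.num_classes), rng)
        self.mlp_b3 = Tensor(np.zeros(config.num_classes), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        params = (
            self.conv1.parameters() + self.pool1.parameters()
            + self.conv2.parameters() + self.pool2.parameters()
            + self.conv3.parameters()
            + [self.mlp_w1, self.mlp_b1, self.mlp_w2, self.mlp_b2, self.mlp_w3, self.mlp_b3]
        )
        if self.config.use_mi:
            params += self.mi1.parameters() + self.mi2.parameters()
        return params

    # -- persistence ---------------------------------------------------

    def state_dict(self) -> dict:
        blob = io.BytesIO()
        arrays = {f"p{i}": p.data for i, p in enumerate(self._all_params())}
        np.savez(blob, **arrays)
        return {"format": "gmaps-model-v1", "config": asdict(self.config), "npz": blob.getvalue()}

    def _all_params(self) -> list[Tensor]:
        # includes MI params regardless of use_mi so save/load is stable
        return (
            self.conv1.parameters() + self.pool1.parameters()
            + self.conv2.parameters() + self.pool2.parameters()
            + self.conv3.parameters()
            + [self.mlp_w1, self.mlp_b1, self.mlp_w2, self.mlp_b2, self.mlp_w3, self.mlp_b3]
            + self.mi1.parameters() + self.mi2.parameters()
        )

    def load_state_dict(self, state: dict) -> None:
        if state.get("format") != "gmaps-model-v1":
            raise ValueError("unrecognized model container format")
        with np.load(io.BytesIO(state["npz"])) as z:
            for i, p in enumerate(self._all_params()):
                p.data = z[f"p{i}"].copy()

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self._all_params()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, d in zip(self._all_params(), snap):
            p.data = d.copy()

    # -- forward -------------------------------------------------------

    def _forward_graph(self, adjacency: np.ndarray, features: np.ndarray):
        """Run the conv/pool stack on one graph (no padding)."""
        a0n = normalize_adjacency(adjacency)
        h1 = self.conv1(Tensor(features), a0n)

        emb1, s1, _ = self.pool1.forward(h1, a0n)
        a1 = coarsen_adjacency(s1, Tensor(adjacency))
        a1n = normalize_adjacency_t(a1)
        h2 = self.conv2(emb1, a1n)

        emb2, s2, _ = self.pool2.forward(h2, a1n)
        a2 = coarsen_adjacency(s2, a1)
        a2n = normalize_adjacency_t(a2)
        h3 = self.conv3(emb2, a2n)

        return [h1, h2, h3], [s1, s2], [emb1, emb2]

    def forward(self, batch: DenseBatch, training: bool = False,
                rng: np.random.Generator | None = None) -> ForwardResult:
        """Class probabilities plus per-layer states and MI losses."""
        if batch.features.shape[2] != self.config.feature_dim:
            raise ValueError(
                f"feature dim mismatch: batch has {batch.features.shape[2]}, "
                f"model expects {self.config.feature_dim}")
        if rng is None:
            rng = np.random.default_rng(0)

        states, assignments, pooled1, pooled2, jk_rows = [], [], [], [], []
        for b in range(batch.batch_size):
            m = batch.mask[b]
            adj = batch.adjacency[b][np.ix_(m, m)]
            feats = batch.features[b][m]
            convs, assigns, pooled = self._forward_graph(adj, feats)
            states.append(convs)
            assignments.append(assigns)
            pooled1.append(pooled[0])
            pooled2.append(pooled[1])
            jk_rows.append(concat([h.mean(axis=0) for h in convs], axis=0))

        jk = concat([row.reshape(1, -1) for row in jk_rows], axis=0)
        probs = self.classify(jk, training=training, rng=rng)

        mi_losses: list[Tensor] = []
        if self.config.use_mi:
            for module, pooled in ((self.mi1, pooled1), (self.mi2, pooled2)):
                negs = corrupt_batch(pooled, rng)
                per_graph = [
                    mi_loss(module, pos, neg, readout_global(pos))
                    for pos, neg in zip(pooled, negs)
                ]
                acc = per_graph[0]
                for t in per_graph[1:]:
                    acc = acc + t
                mi_losses.append(acc * (1.0 / len(per_graph)))

        return ForwardResult(probs, mi_losses, assignments, states, jk)

    def classify(self, jk: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        """MLP head: 3d -> h1 -> h2 -> C with ReLU + dropout, softmax last."""
        if rng is None:
            rng = np.random.default_rng(0)
        rate = self.config.dropout
        x = (jk @ self.mlp_w1 + self.mlp_b1).relu()
        x = dropout(x, rate, rng, training)
        x = (x @ self.mlp_w2 + self.mlp_b2).relu()
        x = dropout(x, rate, rng, training)
        logits = x @ self.mlp_w3 + self.mlp_b3
        return softmax(logits, axis=-1)


# -- losses -------------------------------------------------------------


def cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-probability of the true class."""
    labels = np.asarray(labels, dtype=np.int64)
    picked = probs[np.arange(len(labels)), labels]
    return -(picked.clamp(_CLAMP, 1.0).log().mean())


def total_loss(probs: Tensor, labels: np.ndarray, mi_losses: list[Tensor],
               mi_weight: float) -> Tensor:
    """Cross-entropy plus lambda times the summed per-layer MI losses."""
    loss = cross_entropy(probs, labels)
    for t in mi_losses:
        loss = loss + mi_weight * t
    return loss
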