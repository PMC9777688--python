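"""Graph-reconstruction autoencoder and assignment-matrix export.

The autoencoder measures how much of a graph a pooling layer retains: a
single GCN conv produces node embeddings, one attention pooling layer
compresses them to nc cluster embeddings, and the decoder lifts the
clusters back to nodes through the same layer's soft assignment,
X_rec = S (Z W + b), trained to minimize the mean squared error against
the original node features.  A pooling operator that keeps the graph's
information supports near-exact reconstruction; one that collapses it
cannot beat the single-cluster mean baseline by much.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, glorot_uniform
from .gcn import GCNLayer, normalize_adjacency
from .graph_data import Graph
from .pool import GMAPool

__all__ = ["ReconConfig", "ReconResult", "unpool", "train_reconstruction",
           "export_assignment_heatmap", "mean_row_entropy"]


def unpool(s: Tensor | np.ndarray, x_pool: Tensor | np.ndarray):
    """Lift pooled rows back to nodes: X_rec = S X_pool (numpy in, numpy out)."""
    if isinstance(s, Tensor) or isinstance(x_pool, Tensor):
        s_t, x_t = Tensor._lift(s), Tensor._lift(x_pool)
        if s_t.shape[1] != x_t.shape[0]:
            raise ValueError(f"shape mismatch: S {s_t.shape}, X_pool {x_t.shape}")
        return s_t @ x_t
    s_np, x_np = np.asarray(s, dtype=np.float64), np.asarray(x_pool, dtype=np.float64)
    if s_np.shape[1] != x_np.shape[0]:
        raise ValueError(f"shape mismatch: S {s_np.shape}, X_pool {x_np.shape}")
    return s_np @ x_np


@dataclass
class ReconConfig:
    """Autoencoder settings: one conv + one pooling layer, linear decoder."""

    hidden: int = 32
    heads: int = 4
    pool_ratio: float = 0.25
    lr: float = 5e-4
    max_epochs: int = 5000
    plateau_patience: int = 200      # epochs without 1% relative improvement
    plateau_rtol: float = 0.01
    seed: int = 0


@dataclass
class ReconResult:
    """Reconstruction outcome for one graph."""

    original: np.ndarray
    reconstructed: np.ndarray
    mse: float                  # per-entry mean squared error
    mse_per_node: float         # summed over feature dims, averaged over nodes
    curve: list[float]
    assignment: np.ndarray      # final S, n x nc
    baseline_mse: float         # best achievable with a single mean cluster


def _collapse_baseline(x: np.ndarray) -> float:
    """MSE of the nc=1 optimum: every node reconstructed as the feature mean."""
    return float(((x - x.mean(axis=0)) ** 2).mean())


def train_reconstruction(graph: Graph, config: ReconConfig | None = None) -> ReconResult:
    """Train the conv+pool autoencoder on one graph until plateau.

    Raises FloatingPointError on divergence.  The loss curve records the
    per-entry MSE each epoch; training stops when the best MSE has not
    improved by `plateau_rtol` (relative) within `plateau_patience`
    epochs, or at `max_epochs`.
    """
    if config is None:
        config = ReconConfig()
    if graph.f < 1:
        raise ValueError("graph has no features to reconstruct")
    rng = np.random.default_rng(config.seed)
    n, f, d = graph.n, graph.f, config.hidden
    nc = max(1, math.ceil(config.pool_ratio * n))

    conv = GCNLayer(f, d, rng)
    pool = GMAPool(d, nc, config.heads, rng)
    dec_w = glorot_uniform((d, f), rng)
    dec_b = Tensor(np.zeros(f), requires_grad=True)
    params = conv.parameters() + pool.parameters() + [dec_w, dec_b]
    opt = Adam(params, lr=config.lr)

    a_norm = normalize_adjacency(graph.adjacency)
    x = Tensor(graph.features)

    best = np.inf
    since_improve = 0
    curve: list[float] = []
    for epoch in range(config.max_epochs):
        h = conv(x, a_norm)
        z, s, _ = pool.forward(h, a_norm)
        x_rec = unpool(s, z @ dec_w + dec_b)
        loss = ((x_rec - x) ** 2.0).mean()
        val = float(loss.data)
        if not np.isfinite(val):
            raise FloatingPointError(f"reconstruction diverged at epoch {epoch}")
        curve.append(val)
        if val < best * (1.0 - config.plateau_rtol):
            best = val
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.plateau_patience:
                break
        opt.zero_grad()
        loss.backward()
        opt.step()

    # final forward for the reported reconstruction
    h = conv(x, a_norm)
    z, s, _ = pool.forward(h, a_norm)
    x_rec = unpool(s, z @ dec_w + dec_b).data
    mse = float(((x_rec - graph.features) ** 2).mean())
    return ReconResult(
        original=graph.features.copy(),
        reconstructed=x_rec,
        mse=mse,
        mse_per_node=mse * f,
        curve=curve,
        assignment=s.data.copy(),
        baseline_mse=_collapse_baseline(graph.features),
    )


def mean_row_entropy(s: np.ndarray) -> float:
    """Mean entropy (nats) of row-normalized cluster memberships.

    Quantifies assignment sparsity: 0 for hard one-cluster-per-node
    assignments, log(nc) for perfectly uniform ones.
    """
    s = np.asarray(s, dtype=np.float64)
    rows = s / np.maximum(s.sum(axis=1, keepdims=True), 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rows > 0, rows * np.log(rows), 0.0)
    return float(-terms.sum(axis=1).mean())


def export_assignment_heatmap(s: np.ndarray, path_prefix: str) -> tuple[str, str]:
    """Write S^T (clusters x nodes) as a PNG heatmap and a CSV.

    Returns ``(png_path, csv_path)``.  The CSV stores one cluster per
    row with full float precision, so values round-trip.
    """
    s = np.asarray(s, dtype=np.float64)
    st = s.T
    csv_path = f"{path_prefix}.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"node_{j}" for j in range(st.shape[1])])
        for row in st:
            writer.writerow([repr(float(x)) for x in row])

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, st.shape[1] * 0.2), max(2, st.shape[0] * 0.3)))
    im = ax.imshow(st, aspect="auto", cmap="viridis")
    ax.set_xlabel("node")
    ax.set_ylabel("cluster")
    fig.colorbar(im, ax=ax, label="membership")
    png_path = f"{path_prefix}.png"
    fig.savefig(png_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return png_path, csv_path
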