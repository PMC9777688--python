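"""Graph containers, TUDataset flat-file reading, featurization, batching.

The containers are deliberately plain: a :class:`Graph` is a dense
symmetric adjacency plus a node-feature matrix and an integer class
label, a :class:`GraphDataset` is an ordered list of graphs sharing a
feature dimension, and a :class:`DenseBatch` is the padded, masked stack
used to feed fixed-size models.  All indexing is 0-based internally; the
TUDataset flat-file dialect (1-based, comma-separated) is converted at
the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Graph",
    "GraphDataset",
    "DenseBatch",
    "TUFormatError",
    "read_tudataset",
    "degree_onehot",
    "batch_dense",
    "unbatch",
]


class TUFormatError(ValueError):
    """Raised when a TUDataset flat file is missing or malformed."""


@dataclass
class Graph:
    """One attributed, undirected graph.

    Attributes
    ----------
    adjacency : (n, n) float array, symmetric, zero diagonal on input.
    features : (n, f) float array; f may be 0 before featurization.
    label : integer class index in {0..C-1}, or None (e.g. fixtures).
    """

    adjacency: np.ndarray
    features: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.adjacency.ndim != 2 or self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        if self.adjacency.shape[0] < 1:
            raise ValueError("graph must have at least one node")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if self.features.ndim == 1:
            self.features = self.features.reshape(self.n, -1) if self.features.size else np.zeros((self.n, 0))
        if self.features.shape[0] != self.n:
            raise ValueError("features must have one row per node")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def f(self) -> int:
        return self.features.shape[1]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class GraphDataset:
    """Ordered collection of graphs sharing a feature dimension."""

    graphs: list[Graph]
    num_classes: int

    def __post_init__(self) -> None:
        dims = {g.f for g in self.graphs}
        if len(dims) > 1:
            raise ValueError(f"graphs disagree on feature dimension: {sorted(dims)}")

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self) -> Iterator[Graph]:
        return iter(self.graphs)

    def __getitem__(self, i) -> Graph:
        return self.graphs[i]

    @property
    def feature_dim(self) -> int:
        return self.graphs[0].f if self.graphs else 0

    @property
    def max_nodes(self) -> int:
        return max(g.n for g in self.graphs) if self.graphs else 0

    def labels(self) -> np.ndarray:
        return np.array([g.label for g in self.graphs], dtype=np.int64)

    def subset(self, indices: Sequence[int]) -> "GraphDataset":
        return GraphDataset([self.graphs[i] for i in indices], self.num_classes)


@dataclass
class DenseBatch:
    """Padded stack of graphs: adjacency (B,N,N), features (B,N,f), mask (B,N)."""

    adjacency: np.ndarray
    features: np.ndarray
    mask: np.ndarray
    labels: np.ndarray

    @property
    def batch_size(self) -> int:
        return self.adjacency.shape[0]

    @property
    def num_nodes(self) -> int:
        return self.adjacency.shape[1]

    def graph(self, b: int) -> Graph:
        """Recover graph `b` by stripping padding."""
        m = self.mask[b]
        lab = int(self.labels[b]) if self.labels[b] >= 0 else None
        return Graph(self.adjacency[b][np.ix_(m, m)], self.features[b][m], lab)


# -- TUDataset flat-file reader ----------------------------------------


def _read_int_lines(path: str, what: str) -> np.ndarray:
    try:
        with open(path) as fh:
            return np.array([int(line.strip()) for line in fh if line.strip()], dtype=np.int64)
    except FileNotFoundError:
        raise TUFormatError(f"missing mandatory file for {what}: {path}") from None


def read_tudataset(dir_path: str | os.PathLike, name: str) -> GraphDataset:
    """Read a graph-classification dataset in the TUDataset flat-file layout.

    Expects ``{name}_A.txt`` (1-based edge pairs), ``{name}_graph_indicator.txt``
    and ``{name}_graph_labels.txt`` under `dir_path`; node labels
    (one-hot encoded) or node attributes are used as features when present.
    Edges are symmetrized and deduplicated; labels are remapped to 0..C-1.
    """
    dir_path = os.fspath(dir_path)
    a_path = os.path.join(dir_path, f"{name}_A.txt")
    ind = _read_int_lines(os.path.join(dir_path, f"{name}_graph_indicator.txt"), "graph indicator")
    glabels = _read_int_lines(os.path.join(dir_path, f"{name}_graph_labels.txt"), "graph labels")

    total_nodes = len(ind)
    n_graphs = len(glabels)
    if ind.min() != 1 or ind.max() != n_graphs:
        raise TUFormatError("graph indicator values must be 1..num_graphs and match the label file")

    # per-graph node offsets (nodes are numbered contiguously per graph)
    counts = np.bincount(ind - 1, minlength=n_graphs)
    offsets = np.concatenate([[0], np.cumsum(counts)])

    try:
        with open(a_path) as fh:
            edge_lines = [line.strip() for line in fh if line.strip()]
    except FileNotFoundError:
        raise TUFormatError(f"missing mandatory file for edge list: {a_path}") from None

    adjacencies = [np.zeros((c, c)) for c in counts]
    for lineno, line in enumerate(edge_lines, start=1):
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise TUFormatError(f"{a_path}:{lineno}: expected 'u, v', got {line!r}")
        u, v = int(parts[0]) - 1, int(parts[1]) - 1
        if not (0 <= u < total_nodes and 0 <= v < total_nodes):
            raise TUFormatError(f"{a_path}:{lineno}: edge references unknown node")
        gu, gv = ind[u] - 1, ind[v] - 1
        if gu != gv:
            raise TUFormatError(f"{a_path}:{lineno}: edge crosses graph boundary")
        if u == v:
            continue  # self-loops are added later by normalization, not stored
        lu, lv = u - offsets[gu], v - offsets[gu]
        adjacencies[gu][lu, lv] = 1.0
        adjacencies[gu][lv, lu] = 1.0

    # features: attributes beat node labels; neither -> f=0
    attr_path = os.path.join(dir_path, f"{name}_node_attributes.txt")
    nlab_path = os.path.join(dir_path, f"{name}_node_labels.txt")
    if os.path.exists(attr_path):
        feats = np.loadtxt(attr_path, delimiter=",", ndmin=2)
        if feats.shape[0] != total_nodes:
            raise TUFormatError("node attribute count does not match indicator length")
    elif os.path.exists(nlab_path):
        nlab = _read_int_lines(nlab_path, "node labels")
        values = np.unique(nlab)
        lut = {v: i for i, v in enumerate(values)}
        feats = np.zeros((total_nodes, len(values)))
        feats[np.arange(total_nodes), [lut[v] for v in nlab]] = 1.0
    else:
        feats = np.zeros((total_nodes, 0))

    classes = np.unique(glabels)
    remap = {c: i for i, c in enumerate(classes)}

    graphs = [
        Graph(adjacencies[g], feats[offsets[g]:offsets[g + 1]], remap[glabels[g]])
        for g in range(n_graphs)
    ]
    return GraphDataset(graphs, num_classes=len(classes))


# -- featurization ------------------------------------------------------


def degree_onehot(dataset: GraphDataset, cap: int | None = None, *, override: bool = False) -> GraphDataset:
    """One-hot node degree as the feature, clipped at `cap`.

    Feature dimension is ``cap + 1`` (degrees 0..cap); `cap` defaults to
    the maximum degree in the dataset, i.e. no clipping.  Refuses to
    overwrite existing features unless ``override=True``.
    """
    if dataset.feature_dim > 0 and not override:
        raise ValueError("dataset already has features; pass override=True to replace them")
    if cap is None:
        cap = int(max(g.degrees().max() for g in dataset.graphs))
        cap = max(cap, 1)
    if cap < 1:
        raise ValueError("cap must be >= 1")

    out = []
    for g in dataset.graphs:
        deg = np.minimum(g.degrees().astype(np.int64), cap)
        feats = np.zeros((g.n, cap + 1))
        feats[np.arange(g.n), deg] = 1.0
        out.append(Graph(g.adjacency, feats, g.label))
    return GraphDataset(out, dataset.num_classes)


# -- dense batching ------------------------------------------------------


def batch_dense(graphs: Sequence[Graph]) -> DenseBatch:
    """Stack graphs into a padded batch; padded rows/cols are zero."""
    if len(graphs) == 0:
        raise ValueError("cannot batch zero graphs")
    dims = {g.f for g in graphs}
    if len(dims) > 1:
        raise ValueError("graphs disagree on feature dimension")
    big_n = max(g.n for g in graphs)
    f = graphs[0].f
    B = len(graphs)
    adj = np.zeros((B, big_n, big_n))
    feats = np.zeros((B, big_n, f))
    mask = np.zeros((B, big_n), dtype=bool)
    labels = np.full(B, -1, dtype=np.int64)
    for b, g in enumerate(graphs):
        adj[b, : g.n, : g.n] = g.adjacency
        feats[b, : g.n] = g.features
        mask[b, : g.n] = True
        if g.label is not None:
            labels[b] = g.label
    return DenseBatch(adj, feats, mask, labels)


def unbatch(batch: DenseBatch) -> list[Graph]:
    """Inverse of :func:`batch_dense` (exact round-trip)."""
    return [batch.graph(b) for b in range(batch.batch_size)]
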