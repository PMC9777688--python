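"""Synthetic graph generators and TU-format fixture writers.

Three generators cover the package's test and demonstration needs with
no downloads: a ring graph with 2-D unit-circle coordinates as features
(the reconstruction benchmark), planted-partition graph populations
whose class label is the number of communities (a hierarchical signal a
pooling classifier can learn), and a writer that emits any dataset in
the TUDataset flat-file dialect so the reader can be tested end to end.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np

from .graph_data import Graph, GraphDataset, degree_onehot

__all__ = ["ring_graph", "planted_partition_dataset", "write_tu_fixture"]


def ring_graph(n: int = 64) -> Graph:
    """Cycle graph whose node features are unit-circle coordinates.

    Node i sits at (cos 2*pi*i/n, sin 2*pi*i/n) and connects to its two
    ring neighbours; the graph carries no class label.
    """
    if n < 3:
        raise ValueError("a ring needs at least 3 nodes")
    adj = np.zeros((n, n))
    idx = np.arange(n)
    adj[idx, (idx + 1) % n] = 1.0
    adj[(idx + 1) % n, idx] = 1.0
    theta = 2.0 * np.pi * idx / n
    feats = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return Graph(adj, feats, None)


def planted_partition_dataset(
    n_graphs: int = 200,
    nodes_per_graph: int = 24,
    p_in: float = 0.6,
    p_out: float = 0.1,
    num_classes: int = 2,
    seed: int = 0,
    featurize: bool = True,
) -> GraphDataset:
    """Balanced classes of planted-partition graphs.

    A class-c graph has c+1 equal communities over `nodes_per_graph`
    nodes, with independent within-community edge probability `p_in` and
    between-community probability `p_out`.  Features are degree one-hots
    (as used for featureless social graphs) unless `featurize` is False.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("need 0 <= p_out < p_in <= 1 for separable classes")
    if num_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)

    graphs = []
    for g in range(n_graphs):
        label = g % num_classes
        k = label + 1  # communities
        sizes = [nodes_per_graph // k] * k
        sizes[-1] += nodes_per_graph - sum(sizes)
        G = nx.stochastic_block_model(
            sizes,
            [[p_in if i == j else p_out for j in range(k)] for i in range(k)],
            seed=int(rng.integers(0, 2**31)),
        )
        adj = nx.to_numpy_array(G)
        graphs.append(Graph(adj, np.zeros((nodes_per_graph, 0)), label))

    dataset = GraphDataset(graphs, num_classes)
    if featurize:
        dataset = degree_onehot(dataset)
    return dataset


def write_tu_fixture(dataset: GraphDataset, dir_path: str | os.PathLike, name: str) -> None:
    """Write `dataset` in TUDataset flat-file form (1-based, both edge directions).

    Emits ``{name}_A.txt``, ``{name}_graph_indicator.txt`` and
    ``{name}_graph_labels.txt``; node features are written as
    ``{name}_node_attributes.txt`` when the feature dimension is nonzero.
    ``read_tudataset`` round-trips the output exactly.
    """
    dir_path = os.fspath(dir_path)
    os.makedirs(dir_path, exist_ok=True)
    edge_lines, indicator, labels, attributes = [], [], [], []
    offset = 0
    for g_id, g in enumerate(dataset.graphs, start=1):
        rows, cols = np.nonzero(g.adjacency)
        for u, v in zip(rows, cols):  # both directions, as TU files list them
            edge_lines.append(f"{offset + u + 1}, {offset + v + 1}")
        indicator.extend([str(g_id)] * g.n)
        labels.append(str(g.label if g.label is not None else 0))
        for row in g.features:
            attributes.append(", ".join(repr(float(x)) for x in row))
        offset += g.n

    def _write(fname: str, lines: list[str]) -> None:
        with open(os.path.join(dir_path, fname), "w") as fh:
            fh.write("\n".join(lines) + "\n")

    _write(f"{name}_A.txt", edge_lines)
    _write(f"{name}_graph_indicator.txt", indicator)
    _write(f"{name}_graph_labels.txt", labels)
    if dataset.feature_dim > 0:
        _write(f"{name}_node_attributes.txt", attributes)
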