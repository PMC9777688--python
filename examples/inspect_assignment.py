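"""Inspecting a pooling layer's soft cluster assignment.

Runs one attention pooling layer over a graph made of two loosely
connected communities and exports the assignment matrix S as a heatmap
and CSV (clusters x nodes).  Column sums over nodes are 1 by
construction: the attention weights are normalized per cluster.
"""

import numpy as np

from gmaps import GMAPool, mean_row_entropy, normalize_adjacency, export_assignment_heatmap
from gmaps.autodiff import Tensor

rng = np.random.default_rng(0)

# two 6-node communities with a single bridge
n = 12
adj = np.zeros((n, n))
for block in (range(0, 6), range(6, 12)):
    for i in block:
        for j in block:
            if i < j and rng.random() < 0.8:
                adj[i, j] = adj[j, i] = 1.0
adj[5, 6] = adj[6, 5] = 1.0

features = rng.normal(size=(n, 8))
pool = GMAPool(d=8, nc=3, heads=2, rng=rng)
embeddings, s, _ = pool.forward(Tensor(features), normalize_adjacency(adj))

print(f"assignment S: {s.shape[0]} nodes x {s.shape[1]} clusters")
print(f"column sums (should be 1): {np.round(s.data.sum(axis=0), 6)}")
print(f"mean row entropy: {mean_row_entropy(s.data):.3f} nats "
      f"(0 = hard assignment, {np.log(3):.3f} = uniform)")
png, csv_path = export_assignment_heatmap(s.data, "scratch_assignment")
print(f"wrote {png} and {csv_path}")
# At initialization the assignment is near-uniform; training sharpens it
# so that clusters align with communities.
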