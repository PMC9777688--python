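# Methods

## Model

The package implements graph-level classification with hierarchical
attention pooling. A pooling layer treats clustering as attention: a
learnable seed matrix `Q` (one row per cluster) queries keys and values
generated by GCNs over the current graph, so the attention weights
depend jointly on node features and local structure. Three design points
deserve explicit statement because the written equations of this family
of methods leave them open:

- **Assignment orientation.** Attention produces weights of shape
  `nc × n` whose rows sum to 1 over nodes; the coarsening products
  `S^T H` and `S^T A S` require `S ∈ R^{n×nc}`. We define S as the
  transpose of the head-averaged weight matrix. Normalization is
  therefore **per cluster over nodes** (each column of S sums to 1),
  unlike DiffPool's per-node softmax. Tests assert this direction at
  1e-9.
- **Multihead → single S.** With `h` heads there are `h` weight
  matrices; S averages them before transposing. Averaging is the
  symmetric, parameter-free reduction; deriving S from a designated head
  would break head symmetry for no benefit.
- **Softmax scale.** Each head works in a `d/h`-dimensional subspace and
  uses scale `√(d/h)` (the transformer convention); the single-head
  unprojected form uses `√d`.

Coarsened adjacencies are real-valued and carry self-mass; they are
re-normalized by the same `D̃^{-1/2}(A+I)D̃^{-1/2}` rule before the next
convolution, keeping one code path for raw and pooled graphs (the
differentiable variant lets gradients flow through `A_{k+1}` into S).
All three conv layers apply ReLU, including the last before readout.

The per-conv-layer readout is the masked **mean** (matching the
sigmoid-mean readout the MI module uses and the mean-readout global
baselines this family is compared against); the three readouts are
concatenated (jumping knowledge) and classified by an MLP
`3d → 128 → 56 → C` with ReLU and dropout 0.5 between layers and a
softmax output. Dropout is applied only inside the MLP.

## Mutual-information objective

The self-supervised term is the standard noise-contrastive BCE used by
DGI-style methods:

    L_MI = −(1/(n_pos+n_neg)) [Σ log D(pos, r) + Σ log(1 − D(neg, r))]

with `D(h, r) = σ(h^T W_D r)` and `r` the sigmoid of the mean of the
graph's own pooled embeddings. (Written without the `1−·` in some
presentations, that form is degenerate when maximized; the BCE form is
the objective actually described in words.) The loss is computed after
**each** of the two pooling layers and summed with weight λ = 1.0 by
default — the layer choice and weight are open in the source method; per
layer + unit weight is the least-committal choice and is exposed as
config. Negatives for graph `b` are graph `(b+1) mod B`'s cluster
embeddings; a singleton batch falls back to a seeded row permutation of
the graph's own embeddings. Probabilities are clamped to
`[1e-7, 1−1e-7]` inside the logs.

## Cluster counts

The seed matrix fixes each layer's output size, so `nc` cannot depend on
the per-graph `n`: `nc_1 = max(1, ⌈r · n_ref⌉)` with `n_ref` the
training-set maximum node count, and `nc_2 = max(1, ⌈r · nc_1⌉)`
(deriving `nc_2` from the original `n_ref` instead is a config switch).
Default pooling ratio r = 0.25. Graphs smaller than `nc` still pool
correctly — attention handles `n < nc` without special cases.

## Training protocol

Stratified 80/10/10 splits (scikit-learn, deterministic per seed),
repeated with distinct seeds (10 by default); Adam with lr 5e-4 and
weight decay 1e-4, batch size 128, early stopping on validation accuracy
with patience 50 (ties broken by lower validation loss), best-validation
parameters restored before the single test evaluation. The protocol
reports mean ± std of test accuracy across repeats. Model selection
never touches the test split.

## Numerical engine

No GPU framework is used: `gmaps.autodiff` is a reverse-mode tape over
float64 numpy arrays (broadcast-aware binary ops, matmul, reductions,
softmax with a detached max-shift, layer norm composed from primitives,
clamp with straight-through interior gradient). Masked attention adds
−1e30 to masked logits; after the max-shift the exponential underflows
to exactly 0.0, so masked weights are exactly zero, not merely small.
Batches are stored dense with node masks; the model executes graphs
individually under the mask, which for numpy-sized problems is faster
than padded batched matmuls and keeps shapes honest. Parameters use
variance-scaled (Glorot) uniform init from a seeded generator;
layer-norm epsilon is 1e-5; every source of randomness (init, shuffles,
dropout, corruption) descends from explicit seeds, making runs
bit-reproducible.

## Synthetic data

Two generators define the test conditions:

- **Ring graph** (reconstruction): an N-node cycle (default N = 64) with
  node features `(cos 2πi/N, sin 2πi/N)`. The features are exactly the
  2-D geometry the reconstruction plots show, so the per-entry MSE has a
  direct visual meaning; the feature matrix has rank 2, which is what
  makes near-exact reconstruction through 16 soft clusters possible in
  principle — the experiment measures whether training finds it.
- **Planted partition** (classification): class-c graphs have c+1 equal
  communities over 24 nodes with within-community edge probability 0.6
  and between-community probability 0.1; 200 graphs, balanced labels,
  degree one-hot features. Community count is a hierarchical property —
  precisely what pooling should detect — and also shifts the degree
  distribution, so the task is learnable but not adversarial. These
  graphs emulate small featureless social networks; they do not emulate
  chemical valence structure, long-tailed degree distributions, or
  size variation of real benchmarks, so passing tests show the machinery
  learns hierarchical structure, not that benchmark accuracies transfer.

The TU-format writer emits both edge directions with 1-based indices and
round-trips exactly through the reader (features stored at full float
precision).

## Reconstruction experiment

The autoencoder is one GCN conv (f → d, d = 32) plus one pooling layer
(nc = ⌈0.25 n⌉); the decoder maps cluster embeddings linearly to feature
space and lifts them through the layer's own assignment,
`X_rec = S (Z W + b)`, trained on per-entry MSE with Adam at lr 5e-4 for
at most 5000 epochs, stopping when the best loss has not improved by 1%
(relative) within 200 epochs. A single pooling level keeps the measured
error attributable to the pooling operator alone. Both per-entry and
per-node (×f) MSE are reported, along with the mean row entropy of S as
a sparsity summary and the `nc = 1` mean-collapse baseline
(MSE = feature variance, 0.5 for the unit circle).

## Problem sizes

Desk-scale defaults are used where the computation only needs to
demonstrate the property: hidden size 64 (classification runs in the
acceptance script; the 128 default remains in `ModelConfig`), 60-epoch
cap with patience 50 for the planted-partition run (validation accuracy
saturates within a few epochs on this dataset), hidden 16–32 and rings
of 16–64 nodes in tests. The evaluation protocol itself (splits, early
stopping, restoration, aggregation) is always exercised in full.

## Known limitations

- Dense `n × n` adjacencies: no sparse path, so graphs beyond a few
  thousand nodes are impractical.
- Attention is quadratic in `n` per graph; the engine is single-threaded
  numpy.
- GCN is the only convolution backend; GraphSAGE/GAT variants are out of
  scope.
- The MI objective's layer weighting is a heuristic default, not a tuned
  value.
- `run_protocol` rebuilds the model per repeat with that repeat's seed;
  there is no warm-starting across repeats.
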