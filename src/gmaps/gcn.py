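"""Graph convolution with symmetric normalization.

One layer computes ``act(D̃^{-1/2} (A + I) D̃^{-1/2} H W)`` where Ã = A + I
adds self-loops and D̃ is Ã's degree.  The same normalization rule is
applied to coarsened (real-valued) adjacencies before the next layer, so
there is a single code path for raw and pooled graphs.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, glorot_uniform

__all__ = ["normalize_adjacency", "normalize_adjacency_t", "GCNLayer"]


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Return D̃^{-1/2} (A + I) D̃^{-1/2} for a square nonnegative A.

    The self-loop guarantees strictly positive degrees, so the inverse
    square root is always defined.  Symmetry of A is preserved.
    """
    A = np.asarray(adjacency, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    A_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def normalize_adjacency_t(a: Tensor) -> Tensor:
    """Differentiable form of :func:`normalize_adjacency` for coarsened graphs.

    Gradients flow through the coarsened adjacency (a function of the
    assignment matrix) into the pooling layer that produced it.
    """
    n = a.shape[0]
    a_tilde = a + Tensor(np.eye(n))
    d_inv_sqrt = a_tilde.sum(axis=1) ** -0.5
    return a_tilde * d_inv_sqrt.reshape(n, 1) * d_inv_sqrt.reshape(1, n)


class GCNLayer:
    """A single graph-convolution layer, d_in -> d_out."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, relu: bool = True):
        self.weight = glorot_uniform((d_in, d_out), rng)
        self.relu = relu

    def parameters(self) -> list[Tensor]:
        return [self.weight]

    def __call__(self, h: Tensor, a_norm: np.ndarray | Tensor) -> Tensor:
        """Apply the layer; `a_norm` must already be normalized."""
        a_norm = Tensor._lift(a_norm)
        if h.shape[0] != a_norm.shape[0]:
            raise ValueError(f"node count mismatch: H has {h.shape[0]} rows, A_norm is {a_norm.shape}")
        if h.shape[1] != self.weight.shape[0]:
            raise ValueError(f"feature dim mismatch: H has {h.shape[1]}, layer expects {self.weight.shape[0]}")
        out = a_norm @ h @ self.weight
        return out.relu() if self.relu else out
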