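"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's neural components (GCN layers, multihead attention pooling,
the MI discriminator, the classifier MLP) are small dense computations on
graphs with at most a few hundred nodes, so a compact tape-based engine
over float64 numpy arrays is sufficient and keeps the whole stack
dependency-light.  The public surface is :class:`Tensor`, a handful of
composite ops (softmax, layer_norm, dropout), parameter initialisers and
the :class:`Adam` optimiser.

Gradients follow the usual conventions: broadcasting in the forward pass
is undone by summation in the backward pass; ``Tensor.backward`` seeds the
output with ones and walks the tape in reverse topological order.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "softmax",
    "masked_softmax",
    "layer_norm",
    "dropout",
    "glorot_uniform",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, reversing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev: Sequence["Tensor"] = (), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev = tuple(_prev)
        self.name = name

    # -- bookkeeping --------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'}{tag})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph construction helpers -----------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"]) -> "Tensor":
        needs = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs, _prev=parents if needs else ())
        return out

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = self._make(-self.data, (self,))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = _bwd
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out = self._make(self.data ** p, (self,))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1.0))

        out._backward = _bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = _bwd
        return out

    @property
    def T(self) -> "Tensor":
        out = self._make(self.data.T, (self,))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(out.grad.T)

        out._backward = _bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = self._make(self.data[idx], (self,))

        def _bwd() -> None:
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = _bwd
        return out

    def reshape(self, *shape: int) -> "Tensor":
        out = self._make(self.data.reshape(*shape), (self,))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = _bwd
        return out

    # -- reductions ----------------------------------------------------

    def sum(self, axis: int | tuple[int, ...] | None = None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bwd() -> None:
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bwd
        return out

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------

    def relu(self) -> "Tensor":
        out = self._make(np.maximum(self.data, 0.0), (self,))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0.0))

        out._backward = _bwd
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(s, (self,))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = _bwd
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = self._make(e, (self,))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(out.grad * e)

        out._backward = _bwd
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,))

        def _bwd() -> None:
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _bwd
        return out

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient flows only through the interior."""
        out = self._make(np.clip(self.data, lo, hi), (self,))

        def _bwd() -> None:
            if self.requires_grad:
                inside = (self.data > lo) & (self.data < hi)
                self._accum(out.grad * inside)

        out._backward = _bwd
        return out

    # -- backward pass -------------------------------------------------

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


# -- composite operations ---------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    needs = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=needs, _prev=tensors if needs else ())

    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd() -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])

    out._backward = _bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-shift is treated as a constant: its gradient contribution cancels
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over positions where `mask` is True; masked weights are exactly 0.

    Masked logits receive -1e30 before the shift-and-exponentiate, which
    underflows to exactly 0.0 in float64 after the max-shift.
    """
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), x.shape)
    if not mask.any(axis=axis).all():
        raise ValueError("masked_softmax: at least one position per slice must be unmasked")
    neg = Tensor(np.where(mask, 0.0, -1e30))
    return softmax(x + neg, axis=axis)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis with learnable per-feature gain/bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred ** 2.0).mean(axis=-1, keepdims=True)
    return centred * ((var + eps) ** -0.5) * gain + bias


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = rng.random(x.shape) >= rate
    return x * Tensor(keep / (1.0 - rate))


# -- parameter initialisation and optimisation -------------------------


def glorot_uniform(shape: tuple[int, ...], rng: np.random.Generator) -> Tensor:
    """Variance-scaled uniform init over the last two dims' fan-in/out."""
    fan_in = shape[-2] if len(shape) >= 2 else shape[-1]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam with decoupled L2 weight decay added to the gradient."""

    def __init__(self, params: Iterable[Tensor], lr: float = 5e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
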