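"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The segmentation network in this package runs on CPU at desk scale, so the
engine is deliberately small: a :class:`Tensor` wrapping an ``ndarray``, a
topological backward pass, and the handful of differentiable primitives the
model needs.  Convolution, normalization and the FFT global-convolution
primitives live in :mod:`s5utis.nn.functional`.

Every op returns a new :class:`Tensor`; the graph is define-by-run and is
discarded after :meth:`Tensor.backward`.  Gradients accumulate only on leaf
tensors created with ``requires_grad=True``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _special

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "pow_",
    "exp", "log", "sqrt", "sin", "cos", "tanh", "erf", "atan2", "relu",
    "sum_", "mean", "reshape", "transpose", "concat", "pad2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """NumPy array with optional gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = np.asarray(data, dtype=dtype)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward: Callable | None = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return self.data.item()

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def _tracked(self) -> bool:
        return self.requires_grad or self._backward is not None

    def backward(self, grad=None) -> None:
        """Back-propagate from this tensor; ``grad`` defaults to 1 for scalars."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        # iterative topological order (graphs can be deep)
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
            for p in node._parents:
                if id(p) not in seen and p._tracked():
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if pg is None or not p._tracked():
                    continue
                key = id(p)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def transpose(self, axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_op(data: np.ndarray, parents: Sequence[Tensor], backward: Callable) -> Tensor:
    """Create an op output; drops the graph when no parent is tracked."""
    out = Tensor(data)
    if any(p._tracked() for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data
    return make_op(data, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data - b.data
    return make_op(data, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data
    return make_op(
        data,
        (a, b),
        lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
    )


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data / b.data
    return make_op(
        data,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.shape),
            _unbroadcast(-g * a.data / (b.data * b.data), b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return make_op(-a.data, (a,), lambda g: (-g,))


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p
    return make_op(data, (a,), lambda g: (g * p * a.data ** (p - 1),))


# ---------------------------------------------------------------------------
# elementwise transcendentals
# ---------------------------------------------------------------------------

def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)
    return make_op(data, (a,), lambda g: (g * data,))


def log(a) -> Tensor:
    a = as_tensor(a)
    return make_op(np.log(a.data), (a,), lambda g: (g / a.data,))


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    data = np.sqrt(a.data)
    return make_op(data, (a,), lambda g: (g / (2.0 * data),))


def sin(a) -> Tensor:
    a = as_tensor(a)
    return make_op(np.sin(a.data), (a,), lambda g: (g * np.cos(a.data),))


def cos(a) -> Tensor:
    a = as_tensor(a)
    return make_op(np.cos(a.data), (a,), lambda g: (-g * np.sin(a.data),))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)
    return make_op(data, (a,), lambda g: (g * (1.0 - data * data),))


def erf(a) -> Tensor:
    a = as_tensor(a)
    data = _special.erf(a.data)
    coeff = 2.0 / np.sqrt(np.pi)
    return make_op(data, (a,), lambda g: (g * coeff * np.exp(-a.data * a.data),))


def atan2(a, b) -> Tensor:
    """Elementwise ``arctan2(a, b)`` (a = y-component, b = x-component)."""
    a, b = as_tensor(a), as_tensor(b)
    data = np.arctan2(a.data, b.data)
    denom = a.data * a.data + b.data * b.data

    def backward(g):
        return (
            _unbroadcast(g * b.data / denom, a.shape),
            _unbroadcast(-g * a.data / denom, b.shape),
        )

    return make_op(data, (a, b), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return make_op(a.data * mask, (a,), lambda g: (g * mask,))


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def _expand_reduced(g: np.ndarray, shape: tuple, axis, keepdims: bool) -> np.ndarray:
    if axis is None:
        return np.broadcast_to(g, shape)
    if not keepdims:
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % len(shape) for ax in axes)
        for ax in sorted(axes):
            g = np.expand_dims(g, ax)
    return np.broadcast_to(g, shape)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)
    return make_op(data, (a,), lambda g: (_expand_reduced(g, a.shape, axis, keepdims),))


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / max(data.size, 1)
    return make_op(data, (a,), lambda g: (_expand_reduced(g / n, a.shape, axis, keepdims),))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return make_op(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)
    return make_op(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return make_op(data, ts, backward)


def pad2d(a, pads) -> Tensor:
    """Zero-pad the last two axes; ``pads = (top, bottom, left, right)``."""
    a = as_tensor(a)
    t, b, l, r = pads
    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    data = np.pad(a.data, width)
    H, W = a.shape[-2], a.shape[-1]

    def backward(g):
        return (g[..., t : t + H, l : l + W],)

    return make_op(data, (a,), backward)
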