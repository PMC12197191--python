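"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains a small MLP-Mixer with kernel-discrepancy penalties; all of
that is dense linear algebra on arrays of at most a few thousand elements, so a
compact tape-based engine is sufficient.  A :class:`Tensor` wraps an
``ndarray``; operations record a closure that accumulates gradients into their
inputs.  Only the operations the package actually uses are implemented.

Functions in this module accept either :class:`Tensor` or plain ``ndarray`` /
scalar operands.  Plain operands are treated as constants, which lets the loss
code in :mod:`nirsda.da_losses` run unchanged on numpy inputs (returning
numpy) and on tensors (returning a differentiable tensor).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy import special as _sp_special

__all__ = [
    "Tensor",
    "as_tensor",
    "is_tensor",
    "value_of",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "power",
    "exp",
    "log",
    "erf",
    "gelu",
    "relu",
    "sum",
    "mean",
    "reshape",
    "swapaxes",
    "clip_min",
    "sqrt",
    "take",
    "concatenate",
    "layer_norm",
    "softmax_cross_entropy",
    "log_softmax",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` (shaped by broadcasting) back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    value:
        The numpy array held by this node (stored as float64).
    requires_grad:
        Whether gradients should be accumulated for this node.
    """

    __slots__ = ("value", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value, requires_grad=False)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the recorded tape."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.value)
        # topological order over the reachable graph
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not (parent.requires_grad or parent._backward is not None):
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def as_tensor(x, requires_grad: bool = False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=requires_grad)


def value_of(x) -> np.ndarray:
    """The raw numpy value of a tensor or array-like."""
    if isinstance(x, Tensor):
        return x.value
    return np.asarray(x)


def _node(value, parents: Iterable, backward) -> Tensor:
    """Create a graph node; collapses to a constant when no parent is live."""
    tensor_parents = tuple(p for p in parents if isinstance(p, Tensor))
    live = any(p.requires_grad or p._backward is not None for p in tensor_parents)
    out = Tensor(value)
    if live:
        out._parents = tensor_parents
        out._backward = backward
    return out


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def add(a, b):
    if not _any_tensor(a, b):
        return np.add(a, b)
    a, b = as_tensor(a), as_tensor(b)
    val = a.value + b.value

    def backward(g):
        return ((a, _sum_to_shape(g, a.shape)), (b, _sum_to_shape(g, b.shape)))

    return _node(val, (a, b), backward)


def sub(a, b):
    if not _any_tensor(a, b):
        return np.subtract(a, b)
    a, b = as_tensor(a), as_tensor(b)
    val = a.value - b.value

    def backward(g):
        return ((a, _sum_to_shape(g, a.shape)), (b, _sum_to_shape(-g, b.shape)))

    return _node(val, (a, b), backward)


def neg(a):
    if not _any_tensor(a):
        return np.negative(a)
    return sub(0.0, a)


def mul(a, b):
    if not _any_tensor(a, b):
        return np.multiply(a, b)
    a, b = as_tensor(a), as_tensor(b)
    val = a.value * b.value

    def backward(g):
        return (
            (a, _sum_to_shape(g * b.value, a.shape)),
            (b, _sum_to_shape(g * a.value, b.shape)),
        )

    return _node(val, (a, b), backward)


def div(a, b):
    if not _any_tensor(a, b):
        return np.divide(a, b)
    a, b = as_tensor(a), as_tensor(b)
    val = a.value / b.value

    def backward(g):
        return (
            (a, _sum_to_shape(g / b.value, a.shape)),
            (b, _sum_to_shape(-g * a.value / (b.value**2), b.shape)),
        )

    return _node(val, (a, b), backward)


def power(a, p: float):
    if not _any_tensor(a):
        return np.power(a, p)
    a = as_tensor(a)
    val = a.value**p

    def backward(g):
        return ((a, g * p * a.value ** (p - 1)),)

    return _node(val, (a,), backward)


def matmul(a, b):
    if not _any_tensor(a, b):
        return np.matmul(a, b)
    a, b = as_tensor(a), as_tensor(b)
    val = a.value @ b.value

    def backward(g):
        av, bv = a.value, b.value
        if av.ndim == 1:
            ga = g @ np.swapaxes(bv, -1, -2) if bv.ndim > 1 else g * bv
        else:
            ga = g @ np.swapaxes(bv, -1, -2) if bv.ndim > 1 else np.outer(g, bv)
        if bv.ndim == 1:
            gb = np.swapaxes(av, -1, -2) @ g if av.ndim > 1 else g * av
        else:
            gb = np.swapaxes(av, -1, -2) @ g if av.ndim > 1 else np.outer(av, g)
        return ((a, _sum_to_shape(ga, a.shape)), (b, _sum_to_shape(gb, b.shape)))

    return _node(val, (a, b), backward)


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def exp(a):
    if not _any_tensor(a):
        return np.exp(a)
    a = as_tensor(a)
    val = np.exp(a.value)

    def backward(g):
        return ((a, g * val),)

    return _node(val, (a,), backward)


def log(a):
    if not _any_tensor(a):
        return np.log(a)
    a = as_tensor(a)
    val = np.log(a.value)

    def backward(g):
        return ((a, g / a.value),)

    return _node(val, (a,), backward)


def sqrt(a):
    if not _any_tensor(a):
        return np.sqrt(a)
    return power(a, 0.5)


def erf(a):
    if not _any_tensor(a):
        return _sp_special.erf(a)
    a = as_tensor(a)
    val = _sp_special.erf(a.value)

    def backward(g):
        return ((a, g * (2.0 / np.sqrt(np.pi)) * np.exp(-a.value**2)),)

    return _node(val, (a,), backward)


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a):
    """Exact Gaussian-CDF GELU: ``x * Phi(x)``."""
    if not _any_tensor(a):
        x = np.asarray(a, dtype=np.float64)
        return x * 0.5 * (1.0 + _sp_special.erf(x / _SQRT2))
    a = as_tensor(a)
    x = a.value
    phi = 0.5 * (1.0 + _sp_special.erf(x / _SQRT2))
    val = x * phi

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x**2)
        return ((a, g * (phi + x * pdf)),)

    return _node(val, (a,), backward)


def relu(a):
    if not _any_tensor(a):
        return np.maximum(a, 0.0)
    a = as_tensor(a)
    val = np.maximum(a.value, 0.0)

    def backward(g):
        return ((a, g * (a.value > 0)),)

    return _node(val, (a,), backward)


def clip_min(a, lo: float):
    """Elementwise max(a, lo); gradient passes where a > lo."""
    if not _any_tensor(a):
        return np.maximum(a, lo)
    a = as_tensor(a)
    val = np.maximum(a.value, lo)

    def backward(g):
        return ((a, g * (a.value > lo)),)

    return _node(val, (a,), backward)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def sum(a, axis=None, keepdims=False):  # noqa: A001 - mirrors numpy naming
    if not _any_tensor(a):
        return np.sum(a, axis=axis, keepdims=keepdims)
    a = as_tensor(a)
    val = a.value.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is None:
            ga = np.broadcast_to(g, a.shape).copy()
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            ga = np.broadcast_to(g, a.shape).copy()
        return ((a, ga),)

    return _node(val, (a,), backward)


def mean(a, axis=None, keepdims=False):
    if not _any_tensor(a):
        return np.mean(a, axis=axis, keepdims=keepdims)
    a = as_tensor(a)
    n = a.value.size if axis is None else a.value.shape[axis]
    return div(sum(a, axis=axis, keepdims=keepdims), float(n))


def reshape(a, shape):
    if not _any_tensor(a):
        return np.reshape(a, shape)
    a = as_tensor(a)
    val = a.value.reshape(shape)

    def backward(g):
        return ((a, g.reshape(a.shape)),)

    return _node(val, (a,), backward)


def swapaxes(a, ax1: int, ax2: int):
    if not _any_tensor(a):
        return np.swapaxes(a, ax1, ax2)
    a = as_tensor(a)
    val = np.swapaxes(a.value, ax1, ax2)

    def backward(g):
        return ((a, np.swapaxes(g, ax1, ax2)),)

    return _node(val, (a,), backward)


def take(a, idx):
    """Basic/advanced indexing with gradient scatter-add."""
    if not _any_tensor(a):
        return np.asarray(a)[idx]
    a = as_tensor(a)
    val = a.value[idx]

    def backward(g):
        ga = np.zeros_like(a.value)
        np.add.at(ga, idx, g)
        return ((a, ga),)

    return _node(val, (a,), backward)


def concatenate(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    parts = [as_tensor(p) for p in parts]
    val = np.concatenate([p.value for p in parts], axis=axis)
    sizes = [p.value.shape[axis] for p in parts]

    def backward(g):
        outs = []
        offsets = np.cumsum([0] + sizes)
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            outs.append((p, g[tuple(sl)]))
        return tuple(outs)

    return _node(val, tuple(parts), backward)


# ---------------------------------------------------------------------------
# composite neural-network ops
# ---------------------------------------------------------------------------

def layer_norm(x, gain, bias, eps: float = 1e-5):
    """Normalize over the last axis, then scale and shift.

    ``gain``/``bias`` broadcast against the last axis of ``x``.
    """
    mu = mean(x, axis=-1, keepdims=True)
    centered = sub(x, mu)
    var = mean(mul(centered, centered), axis=-1, keepdims=True)
    inv = power(add(var, eps), -0.5)
    return add(mul(mul(centered, inv), gain), bias)


def log_softmax(logits):
    """Row-wise log-softmax over the last axis (max-shifted for stability)."""
    shift = value_of(logits).max(axis=-1, keepdims=True)  # constant shift
    z = sub(logits, shift)
    lse = log(sum(exp(z), axis=-1, keepdims=True))
    return sub(z, lse)


def softmax_cross_entropy(logits, labels: np.ndarray):
    """Mean softmax cross-entropy of integer ``labels`` given ``logits`` [n, M]."""
    labels = np.asarray(labels)
    n = value_of(logits).shape[0]
    lp = log_softmax(logits)
    picked = take(lp, (np.arange(n), labels))
    return neg(mean(picked))
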