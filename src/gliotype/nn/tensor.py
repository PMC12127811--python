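"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core the network is built on: a :class:`Tensor` wraps an
``ndarray`` and records, while gradients are enabled, the operations that
produced it.  ``Tensor.backward()`` then runs the reverse sweep in topological
order.  The op set is exactly what the model needs (elementwise arithmetic,
matmul, reductions, softmax/logsumexp, shape surgery and 3-D convolution); it
is not a general framework.

Gradients follow numpy broadcasting: a gradient flowing into a broadcast
operand is summed back to the operand's shape.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- backward sweep ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad) if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for p, g in zip(node._parents, grads):
                if g is None or not p.requires_grad:
                    continue
                if p.grad is None:
                    p.grad = g
                else:
                    p.grad = p.grad + g
            if node is not self:
                # free intermediate gradients/graph as we go
                node.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    # python-number operands take a scalar fast path: numpy does not promote
    # float32 arrays for python scalars, and the backward is trivial
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data + other, (self,), lambda g: (g,))
        other = as_tensor(other)
        data = self.data + other.data

        def bw(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data * other, (self,), lambda g: (g * other,))
        other = as_tensor(other)
        data = self.data * other.data

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        data = self.data / other.data

        def bw(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, n: float):
        data = self.data**n

        def bw(g):
            return (g * n * self.data ** (n - 1),)

        return Tensor._make(data, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        data = self.data @ other.data

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(data, (self, other), bw)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        data = np.exp(self.data)
        return Tensor._make(data, (self,), lambda g: (g * data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        data = np.sqrt(self.data)
        return Tensor._make(data, (self,), lambda g: (g / (2.0 * data),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(
            np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,)
        )

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(data, (self,), lambda g: (g * data * (1.0 - data),))

    def clip_min(self, lo: float):
        """Lower clamp; gradient passes only where the input is above ``lo``."""
        mask = self.data > lo
        return Tensor._make(
            np.maximum(self.data, lo), (self,), lambda g: (g * mask,)
        )

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._make(data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient routes to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            data = np.squeeze(data, axis=axis)

        def bw(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            out = np.zeros_like(self.data)
            np.put_along_axis(out, np.expand_dims(idx, axis), g2, axis=axis)
            return (out,)

        return Tensor._make(data, (self,), bw)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        # clamp avoids subnormal exp() results (orders of magnitude slower on
        # x86); exp(-80) ~ 1.8e-35 is negligible against the max term's 1.0
        e = np.exp(np.maximum(self.data - m, -80.0))
        s = e.sum(axis=axis, keepdims=True)
        data = (m + np.log(s))
        soft = e / s
        if not keepdims:
            data = np.squeeze(data, axis=axis)

        def bw(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (g2 * soft,)

        return Tensor._make(data, (self,), bw)

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(np.maximum(self.data - m, -80.0))  # see logsumexp
        data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * data).sum(axis=axis, keepdims=True)
            return ((g - dot) * data,)

        return Tensor._make(data, (self,), bw)

    # -- shape surgery ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        return Tensor._make(data, (self,), lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        data = self.data.transpose(axes)
        return Tensor._make(data, (self,), lambda g: (g.transpose(inv),))

    def __getitem__(self, key):
        data = self.data[key]

        def bw(g):
            out = np.zeros_like(self.data)
            out[key] = g
            return (out,)

        return Tensor._make(data, (self,), bw)

    def gather(self, index: np.ndarray, axis: int):
        """take_along_axis with scatter-add backward (class-probability lookup)."""
        index = np.asarray(index)
        data = np.take_along_axis(self.data, index, axis=axis)

        def bw(g):
            out = np.zeros_like(self.data)
            np.put_along_axis(out, index, g, axis=axis)
            return (out,)

        return Tensor._make(data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tensors, bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(data, tensors, bw)
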