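"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network, losses and optimizer in this package are defined on
:class:`Tensor`, a thin float64 wrapper around ``numpy.ndarray`` that
records the computation graph and supports backpropagation.  Only the
operations the dual-stream model needs are implemented (elementwise
arithmetic with broadcasting, matmul, tanh/sigmoid/exp/log, reductions,
cumulative sums, concatenation and slicing).  Gradients are accumulated
in ``Tensor.grad`` by :meth:`Tensor.backward`, which walks a topological
order of the recorded graph.

All data is coerced to float64 so that analytic gradients can be
validated against central finite differences to tight tolerances.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "cat", "stack", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph holding a float64 array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self.name = name

    # ------------------------------------------------------------------ utils
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name}" if self.name else ""
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad}{tag})"

    # ------------------------------------------------------------ graph build
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def backward(g):
            self._accum(-g)

        out._backward = backward if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        out._backward = backward if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        assert isinstance(p, (int, float))
        out = self._make(self.data ** p, (self,), None)

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1 and self.data.ndim >= 1:
                    self._accum(np.multiply.outer(g, other.data)
                                if g.ndim else g * other.data)
                else:
                    self._accum(g @ np.swapaxes(other.data, -1, -2)
                                if g.ndim else np.outer(g, other.data))
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accum(np.multiply.outer(self.data, g)
                                 if g.ndim else self.data * g)
                else:
                    other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = backward if out.requires_grad else None
        return out

    # ------------------------------------------------------------ elementwise
    def tanh(self):
        y = np.tanh(self.data)
        out = self._make(y, (self,), None)

        def backward(g):
            self._accum(g * (1.0 - y * y))

        out._backward = backward if out.requires_grad else None
        return out

    def sigmoid(self):
        y = np.empty_like(self.data)
        pos = self.data >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        y[~pos] = e / (1.0 + e)
        out = self._make(y, (self,), None)

        def backward(g):
            self._accum(g * y * (1.0 - y))

        out._backward = backward if out.requires_grad else None
        return out

    def exp(self):
        y = np.exp(self.data)
        out = self._make(y, (self,), None)

        def backward(g):
            self._accum(g * y)

        out._backward = backward if out.requires_grad else None
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            self._accum(g / self.data)

        out._backward = backward if out.requires_grad else None
        return out

    def sqrt(self):
        return self ** 0.5

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = self._make(self.data.reshape(shape), (self,), None)

        def backward(g):
            self._accum(g.reshape(orig))

        out._backward = backward if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = backward if out.requires_grad else None
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            g = np.asarray(g, dtype=np.float64)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def cumsum(self, axis: int = 0):
        out = self._make(np.cumsum(self.data, axis=axis), (self,), None)

        def backward(g):
            # adjoint of cumsum is reversed cumsum
            rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
            self._accum(rev)

        out._backward = backward if out.requires_grad else None
        return out

    # ---------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise ValueError("called backward on a tensor that requires no grad")
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def cat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis` (differentiable)."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis (differentiable)."""
    expanded = []
    ax = None
    for t in tensors:
        t = Tensor._lift(t)
        shape = list(t.data.shape)
        ax = axis if axis >= 0 else axis + len(shape) + 1
        shape.insert(ax, 1)
        expanded.append(t.reshape(shape))
    return cat(expanded, axis=ax)


def softmax(scores: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from graph primitives."""
    shift = Tensor(scores.data.max(axis=axis, keepdims=True))
    e = (scores - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
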