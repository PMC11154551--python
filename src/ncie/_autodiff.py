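"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small recurrent generators and statistics networks whose
loss (a Donsker-Varadhan bound) must back-propagate *through* the generated
implicit series into the generator.  This module provides just enough of a
tape-based autodiff engine for that: broadcast-aware elementwise arithmetic,
matrix products, tanh/sigmoid/exp/log, reductions, concatenation and fancy
row indexing, plus an Adam optimizer.  Everything is float64 and
single-threaded-deterministic.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence[tuple["Tensor", Callable]] = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in _parents)
        # keep the tape only when a gradient can flow
        self._parents = tuple(_parents) if self.requires_grad else ()
        self.grad: np.ndarray | None = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        return Tensor(self.data + other.data, _parents=(
            (self, lambda g: _unbroadcast(g, self.shape)),
            (other, lambda g: _unbroadcast(g, other.shape)),
        ))

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, _parents=((self, lambda g: -g),))

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        return Tensor(self.data * other.data, _parents=(
            (self, lambda g: _unbroadcast(g * other.data, self.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.shape)),
        ))

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        return Tensor(self.data / other.data, _parents=(
            (self, lambda g: _unbroadcast(g / other.data, self.shape)),
            (other, lambda g: _unbroadcast(-g * self.data / other.data ** 2,
                                           other.shape)),
        ))

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor(self.data ** exponent, _parents=(
            (self, lambda g: g * exponent * self.data ** (exponent - 1)),
        ))

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        return Tensor(self.data @ other.data, _parents=(
            (self, lambda g: g @ other.data.T),
            (other, lambda g: self.data.T @ g),
        ))

    # -- elementwise functions -------------------------------------------
    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor(out, _parents=((self, lambda g: g * out),))

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data),
                      _parents=((self, lambda g: g / self.data),))

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        return Tensor(out, _parents=((self, lambda g: g * (1.0 - out ** 2)),))

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, _parents=((self, lambda g: g * out * (1.0 - out)),))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(self.data * mask, _parents=((self, lambda g: g * mask),))

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.shape).copy()
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _parents=((self, vjp),))

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        return Tensor(self.data.reshape(*shape), _parents=(
            (self, lambda g: g.reshape(self.shape)),))

    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Row gather (first axis).  Gradient scatters with accumulation."""
        index = np.asarray(index)

        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, index, g)
            return out
        return Tensor(self.data[index], _parents=((self, vjp),))

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        def vjp(g):
            out = np.zeros_like(self.data)
            out[:, start:stop] = g
            return out
        return Tensor(self.data[:, start:stop], _parents=((self, vjp),))

    # -- backward ---------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep RNN tapes overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, vjp in node._parents:
                if not parent.requires_grad:
                    continue
                g = vjp(node.grad)
                parent.grad = g if parent.grad is None else parent.grad + g


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    offset = 0
    for t in tensors:
        width = t.data.shape[axis]
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(offset, offset + width)
        parents.append((t, lambda g, sl=tuple(sl): g[sl]))
        offset += width
    return Tensor(data, _parents=parents)


class Adam:
    """Adam with bias correction; operates on leaf Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
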