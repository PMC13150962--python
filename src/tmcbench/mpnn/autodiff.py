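"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the message-passing network needs: affine
maps, elementwise arithmetic, shifted-softplus, row gather/scatter (graph
message passing), segment pooling, norms and L1 loss. Gradients accumulate
into ``Tensor.grad``; call :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "gather", "scatter_sum", "ssp"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not (t.requires_grad or t._parents):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)

        def bwd(g):
            self._needs(g) and self._accumulate(_unbroadcast(g, self.shape))
            other._needs(g) and other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = _wrap(other)

        def bwd(g):
            self._needs(g) and self._accumulate(_unbroadcast(g, self.shape))
            other._needs(g) and other._accumulate(-_unbroadcast(g, other.shape))

        return Tensor(self.data - other.data, parents=(self, other), backward=bwd)

    def __rsub__(self, other):
        return _wrap(other).__sub__(self)

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __mul__(self, other):
        other = _wrap(other)

        def bwd(g):
            self._needs(g) and self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._needs(g) and other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _wrap(other)

        def bwd(g):
            self._needs(g) and self._accumulate(g @ other.data.T)
            other._needs(g) and other._accumulate(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def _needs(self, _g) -> bool:
        return self.requires_grad or bool(self._parents)

    # -- reductions / elementwise ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            self._accumulate(np.full(self.shape, float(g) / n))

        return Tensor(self.data.mean(), parents=(self,), backward=bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accumulate(g * sign)

        return Tensor(np.abs(self.data), parents=(self,), backward=bwd)

    def sqrt(self, eps: float = 1e-12):
        root = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / np.maximum(root, eps))

        return Tensor(root, parents=(self,), backward=bwd)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def ssp(x: Tensor) -> Tensor:
    """Shifted softplus log(0.5 eˣ + 0.5) — smooth, ssp(0) = 0."""
    out = np.logaddexp(0.0, x.data) - np.log(2.0)
    sig = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accumulate(g * sig)

    return Tensor(out, parents=(x,), backward=bwd)


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather x[idx]; scatters the gradient back with accumulation."""

    def bwd(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accumulate(acc)

    return Tensor(x.data[idx], parents=(x,), backward=bwd)


def scatter_sum(x: Tensor, idx: np.ndarray, n_out: int) -> Tensor:
    """Segment sum: out[k] = Σ_{i: idx[i]=k} x[i] (rows)."""
    out = np.zeros((n_out,) + x.data.shape[1:])
    np.add.at(out, idx, x.data)

    def bwd(g):
        x._accumulate(g[idx])

    return Tensor(out, parents=(x,), backward=bwd)
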