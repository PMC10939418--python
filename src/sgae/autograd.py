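"""Minimal reverse-mode automatic differentiation over numpy arrays.

The Siamese graph autoencoder is trained full-batch on dense/sparse matrix
products, so a small define-by-run tape over numpy is sufficient: every
operation records a closure that accumulates gradients into its parents.
Only the operations the model needs are implemented. Gradients are exact
(analytic), which the test suite verifies against central finite differences.

Sparse constant matrices (scipy.sparse) are supported as the left operand of
``spmm`` since adjacency operators never require gradients.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "as_tensor", "spmm", "relu", "sigmoid"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _acc(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._acc(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._acc(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._acc(g @ other.data.T)
            if other.requires_grad:
                other._acc(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._acc(g * exponent * self.data ** (exponent - 1.0))

        return self._make(self.data**exponent, (self,), backward)

    # -- shape / reductions ---------------------------------------------------
    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self._acc(g.T)

        return self._make(self.data.T, (self,), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._acc(np.full_like(self.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._acc(np.broadcast_to(gg, self.shape).copy())

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    # -- elementwise nonlinearities ------------------------------------------
    def log(self):
        def backward(g):
            if self.requires_grad:
                self._acc(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._acc(g * out_data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def spmm(a_const, x: Tensor) -> Tensor:
    """Product ``a_const @ x`` where a_const is a constant (sparse or dense).

    No gradient flows into a_const; d(loss)/dx = a_const.T @ upstream.
    """
    x = as_tensor(x)
    a_t = a_const.T

    def backward(g):
        if x.requires_grad:
            x._acc(np.asarray(a_t @ g))

    out = Tensor(np.asarray(a_const @ x.data))
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        out._parents = (x,)
        out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._acc(g * mask)

    return x._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._acc(g * out_data * (1.0 - out_data))

    return x._make(out_data, (x,), backward)


def identity(x: Tensor) -> Tensor:
    return as_tensor(x)


ACTIVATIONS = {"relu": relu, "identity": identity, "linear": identity,
               "sigmoid": sigmoid}
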