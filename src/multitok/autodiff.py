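"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core under the sequence encoders and classifier heads:
a tape-based scalar-loss autodiff engine supporting exactly the operations
those models need (broadcast arithmetic, matmul, softmax/log-softmax, tanh,
relu, reductions, reshape/transpose/concatenate, and embedding-row gather).
Gradients are accumulated in float64 and are verified against central finite
differences in the test suite.

The API is deliberately tiny: wrap arrays in :class:`Tensor`, compose, call
``backward()`` on a scalar, read ``.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _init_grad(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)

    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def backward(self):
        """Backpropagate from a scalar node through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self._init_grad()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._init_grad()
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other._init_grad()
                other.grad += _unbroadcast(g, other.shape)

        return self._make(self.data + other.data, (self, other), backward, out_req)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._init_grad()
            self.grad += -g

        return self._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._init_grad()
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other._init_grad()
                other.grad += _unbroadcast(g * self.data, other.shape)

        return self._make(self.data * other.data, (self, other), backward, out_req)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            self._init_grad()
            self.grad += g * exponent * self.data ** (exponent - 1)

        return self._make(self.data ** exponent, (self,), backward, self.requires_grad)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._init_grad()
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self.grad += _unbroadcast(ga, self.shape)
            if other.requires_grad:
                other._init_grad()
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other.grad += _unbroadcast(gb, other.shape)

        return self._make(np.matmul(self.data, other.data), (self, other), backward, out_req)

    # -- nonlinearities ---------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            self._init_grad()
            self.grad += g * (1.0 - y * y)

        return self._make(y, (self,), backward, self.requires_grad)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._init_grad()
            self.grad += g * mask

        return self._make(self.data * mask, (self,), backward, self.requires_grad)

    def exp(self):
        y = np.exp(self.data)

        def backward(g):
            self._init_grad()
            self.grad += g * y

        return self._make(y, (self,), backward, self.requires_grad)

    def log(self):
        def backward(g):
            self._init_grad()
            self.grad += g / self.data

        return self._make(np.log(self.data), (self,), backward, self.requires_grad)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis``."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            self._init_grad()
            dot = (g * y).sum(axis=axis, keepdims=True)
            self.grad += y * (g - dot)

        return self._make(y, (self,), backward, self.requires_grad)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse
        sm = np.exp(y)

        def backward(g):
            self._init_grad()
            self.grad += g - sm * g.sum(axis=axis, keepdims=True)

        return self._make(y, (self,), backward, self.requires_grad)

    # -- reductions & shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            self._init_grad()
            if axis is None:
                self.grad += g  # g is scalar-shaped, broadcasts
            elif keepdims:
                self.grad += g
            else:
                self.grad += np.expand_dims(g, axis)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,),
                          backward, self.requires_grad)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            self._init_grad()
            self.grad += g.reshape(old)

        return self._make(self.data.reshape(*shape), (self,), backward, self.requires_grad)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._init_grad()
            self.grad += g.transpose(*inv)

        return self._make(self.data.transpose(*axes), (self,), backward, self.requires_grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out_req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._init_grad()
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return Tensor._make(data, tuple(tensors), backward, out_req)


def gather_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Select rows ``table[indices]`` (embedding lookup) with scatter-add grad."""
    idx = np.asarray(indices)

    def backward(g):
        table._init_grad()
        np.add.at(table.grad, idx, g)

    return Tensor._make(table.data[idx], (table,), backward, table.requires_grad)
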