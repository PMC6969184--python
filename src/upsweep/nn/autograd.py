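"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray; arithmetic builds a DAG of parent
tensors with closure-recorded backward rules.  ``Tensor.backward()``
topologically sorts the graph and accumulates gradients into ``.grad``.
Gradients flow only into tensors created with ``requires_grad=True`` (and
through any intermediate node on a path to one).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph construction -------------------------------------------------

    @classmethod
    def _node(cls, data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    # -- elementwise arithmetic ---------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - t * t),)

        return Tensor._node(t, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * s * (1.0 - s),)

        return Tensor._node(s, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._node(self.data * mask, (self,), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._node(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(*inv),)

        return Tensor._node(self.data.transpose(*axes), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        orig = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, orig).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, orig).copy(),)

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- linear algebra -------------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        a, b = self.data, other.data
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def backward(g):
            return (g @ b.T, a.T @ g)

        return Tensor._node(a @ b, (self, other), backward)

    __matmul__ = matmul

    # -- autodiff -------------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or node._backward is None:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            grads = node._backward(node.grad)
            for parent, g in zip(node._prev, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += g

    def zero_grad(self):
        self.grad = None


def take(x: Tensor, index: int, axis: int = 1) -> Tensor:
    """Select one slice along ``axis`` (used to step a GRU through time)."""
    data = np.take(x.data, index, axis=axis)

    def backward(g):
        gx = np.zeros_like(x.data)
        sl = [slice(None)] * x.data.ndim
        sl[axis] = index
        gx[tuple(sl)] = g
        return (gx,)

    return Tensor._node(data, (x,), backward)


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Stack tensors along a new axis (used to assemble GRU output sequences)."""
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._node(data, tuple(tensors), backward)
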