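"""Minimal reverse-mode automatic differentiation over numpy arrays.

The MIL networks in this package are small (a few thousand parameters,
one attention layer) and are trained one bag at a time, so a compact
tape-based engine is sufficient. Every ``Tensor`` wraps a float64
ndarray; operations record a backward closure, and :meth:`Tensor.backward`
walks the tape in reverse topological order.

Gradients are accumulated in ``Tensor.grad`` only for tensors created
with ``requires_grad=True`` or depending on one. Broadcasting follows
numpy semantics; ``_unbroadcast`` sums gradients back to the operand
shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "relu", "tanh", "sigmoid", "softplus"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
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
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            return ((self, -g),)
        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def bw(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def bw(g):
            return ((self, _unbroadcast(g / other.data, self.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return Tensor(self.data ** p, _parents=(self,), _backward=bw)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.shape)),
                    (other, _unbroadcast(gb, other.shape)))

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def bw(g):
            return ((self, g.reshape(orig)),)

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bw)

    @property
    def T(self):
        def bw(g):
            return ((self, np.swapaxes(g, -1, -2)),)
        return Tensor(np.swapaxes(self.data, -1, -2), _parents=(self,), _backward=bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            return ((self, np.transpose(g, inv)),)

        return Tensor(np.transpose(self.data, axes), _parents=(self,), _backward=bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            return ((self, g * out_data),)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def log(self):
        def bw(g):
            return ((self, g / self.data),)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bw(g):
        return ((x, g * (1.0 - out_data ** 2)),)

    return Tensor(out_data, _parents=(x,), _backward=bw)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable logistic

    def bw(g):
        return ((x, g * out_data * (1.0 - out_data)),)

    return Tensor(out_data, _parents=(x,), _backward=bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        return ((x, g * mask),)

    return Tensor(x.data * mask, _parents=(x,), _backward=bw)


def softplus(x: Tensor) -> Tensor:
    out_data = np.logaddexp(0.0, x.data)

    def bw(g):
        return ((x, g * 0.5 * (1.0 + np.tanh(0.5 * x.data))),)

    return Tensor(out_data, _parents=(x,), _backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtracting the detached max is exact for softmax and keeps exp() finite
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        outs = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            outs.append((t, g[tuple(sl)]))
        return tuple(outs)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=bw)
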