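"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine tailored to what the survival GNN needs: dense
matmul, broadcasting elementwise arithmetic, the usual nonlinearities,
axis reductions (including max with subgradient to the first argmax), and
scalar stacking for assembling per-slide risk scores into a cohort vector.
Everything is float64 so analytic gradients can be checked against central
finite differences to tight tolerances.

Usage mirrors the familiar pattern::

    x = Tensor(np.ones((3, 2)), requires_grad=True)
    y = (x @ w + b).relu().sum()
    y.backward()
    x.grad  # ndarray, same shape as x.data
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "stack", "where_const"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g, b.data.shape))
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._from_op(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g * a.data, b.data.shape))
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._from_op(self.data**exponent, (self,), None)
        if out.requires_grad:
            def backward(g, a=self, p=exponent):
                a._accum(g * p * a.data ** (p - 1))
            out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                ad, bd = a.data, b.data
                if a.requires_grad:
                    if ad.ndim == 1 and bd.ndim == 1:
                        a._accum(g * bd)
                    elif ad.ndim == 1:
                        a._accum(g @ bd.T)
                    elif bd.ndim == 1:
                        a._accum(np.outer(g, bd) if g.ndim == 1 else g[..., None] * bd)
                    else:
                        a._accum(_unbroadcast(g @ np.swapaxes(bd, -1, -2), ad.shape))
                if b.requires_grad:
                    if ad.ndim == 1 and bd.ndim == 1:
                        b._accum(g * ad)
                    elif bd.ndim == 1:
                        b._accum(ad.T @ g if g.ndim >= 1 and ad.ndim > 1 else g * ad)
                    elif ad.ndim == 1:
                        b._accum(np.outer(ad, g))
                    else:
                        b._accum(_unbroadcast(np.swapaxes(ad, -1, -2) @ g, bd.shape))
            out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Tensor._from_op(e, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self, e=e: a._accum(g * e)
        return out

    def log(self):
        out = Tensor._from_op(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor._from_op(t, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self, t=t: a._accum(g * (1.0 - t * t))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._from_op(s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self, s=s: a._accum(g * s * (1.0 - s))
        return out

    def relu(self):
        out = Tensor._from_op(np.maximum(self.data, 0.0), (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * (a.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor._from_op(np.where(self.data > 0, self.data, slope * self.data), (self,), None)
        if out.requires_grad:
            def backward(g, a=self, s=slope):
                a._accum(g * np.where(a.data > 0, 1.0, s))
            out._backward = backward
        return out

    def abs(self):
        out = Tensor._from_op(np.abs(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * np.sign(a.data))
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims: bool = False):
        """Max reduction; the subgradient flows to the first argmax only."""
        data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor._from_op(data, (self,), None)
        if out.requires_grad:
            def backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is None:
                    grad = np.zeros_like(a.data)
                    grad[np.unravel_index(np.argmax(a.data), a.data.shape)] = np.sum(g)
                    a._accum(grad)
                else:
                    idx = np.argmax(a.data, axis=axis)
                    grad = np.zeros_like(a.data)
                    gg = g if keepdims is False else np.squeeze(g, axis=axis)
                    np.put_along_axis(
                        grad, np.expand_dims(idx, axis), np.expand_dims(gg, axis), axis
                    )
                    a._accum(grad)
            out._backward = backward
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor._from_op(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    @property
    def T(self):
        out = Tensor._from_op(self.data.T, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.T)
        return out

    def __getitem__(self, idx):
        out = Tensor._from_op(self.data[idx], (self,), None)
        if out.requires_grad:
            def backward(g, a=self, idx=idx):
                grad = np.zeros_like(a.data)
                np.add.at(grad, idx, g)
                a._accum(grad)
            out._backward = backward
        return out

    # -- autograd machinery ---------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def stack(tensors) -> Tensor:
    """Stack scalar (or equal-shape) tensors along a new leading axis."""
    tensors = list(tensors)
    out = Tensor._from_op(np.stack([t.data for t in tensors]), tuple(tensors), None)
    if out.requires_grad:
        def backward(g, ts=tensors):
            for i, t in enumerate(ts):
                if t.requires_grad:
                    t._accum(g[i])
        out._backward = backward
    return out


def where_const(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select with a constant boolean condition."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    out = Tensor._from_op(np.where(cond, a.data, b.data), (a, b), None)
    if out.requires_grad:
        def backward(g, a=a, b=b, cond=cond):
            if a.requires_grad:
                a._accum(_unbroadcast(np.where(cond, g, 0.0), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.where(cond, 0.0, g), b.data.shape))
        out._backward = backward
    return out
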