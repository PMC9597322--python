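"""Compact reverse-mode tensor autodiff on numpy arrays.

Implements exactly the operations the growth-prediction network needs:
broadcast-aware arithmetic, batched matmul, reshape/transpose, softmax,
layer normalization, GELU, reductions, concatenation and row gather.
Gradients flow through a topologically sorted tape; broadcasting is
undone by summing gradients over the broadcast axes.

All arrays are float64 by default (float32 inputs are upcast); the
engine is deliberately small and fully gradient-checked in the test
suite rather than feature-complete.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking arithmetic

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------
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
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
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
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar: dtype-preserving
            a, c = self, other

            def back_s(g):
                a._accum(g)

            return self._make(a.data + c, (a,), back_s)
        a, b = self, self._wrap(other)

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            a._accum(-g)

        return self._make(-a.data, (a,), back)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):  # scalar: dtype-preserving
            a, c = self, other

            def back_s(g):
                a._accum(g * c)

            return self._make(a.data * c, (a,), back_s)
        a, b = self, self._wrap(other)

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        a, b = self, self._wrap(other)

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), back)

    def __matmul__(self, other):
        a, b = self, self._wrap(other)

        def back(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.shape))

        return self._make(np.matmul(a.data, b.data), (a, b), back)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = a.shape

        def back(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), back)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)

        def back(g):
            a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), back)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def back(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims=False):
        a = self
        n = a.data.size if axis is None else np.prod(
            [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return a.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ------------------------------------------------
    def gelu(self):
        """Sigmoid-form GELU approximation ``x * sigmoid(1.702 x)``.

        Within ~1% of the erf GELU, one transcendental per element.
        """
        a = self
        x = a.data
        s = np.exp(-1.702 * x)
        s += 1.0
        np.reciprocal(s, out=s)

        def back(g):
            a._accum(g * (s + 1.702 * x * s * (1.0 - s)))

        return self._make(x * s, (a,), back)

    def softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        s = np.exp(z, out=z)
        s /= s.sum(axis=axis, keepdims=True)

        def back(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

        return self._make(s, (a,), back)

    def layer_norm(self, eps: float = 1e-6):
        """Normalize the last axis to zero mean / unit variance."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        xc = a.data - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        n = a.shape[-1]

        def back(g):
            gm = g.mean(axis=-1, keepdims=True)
            gx = (g * xhat).mean(axis=-1, keepdims=True)
            a._accum(inv * (g - gm - xhat * gx))

        return self._make(xhat, (a,), back)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along ``axis`` with gradient splitting."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(gpart)

        out._parents = tuple(tensors)
        out._backward = back
    return out


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of a 2D+ tensor; gradient scatter-adds back."""
    index = np.asarray(index, dtype=int)
    out = Tensor(t.data[index])
    out.requires_grad = t.requires_grad
    if t.requires_grad:
        def back(g):
            gt = np.zeros_like(t.data)
            np.add.at(gt, index, g)
            t._accum(gt)

        out._parents = (t,)
        out._backward = back
    return out
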