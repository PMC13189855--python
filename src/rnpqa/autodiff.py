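"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the quality-assessment network needs:
dense linear algebra, elementwise nonlinearities, row gather / segment
scatter for message passing, (masked) softmax, and reductions. Float64
throughout; gradients accumulate into ``Tensor.grad`` after ``backward()``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "segment_sum", "segment_softmax", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            ga = g @ b.T if b.ndim == 2 else np.outer(g, b)
            gb = a.T @ g if a.ndim == 2 else np.outer(a, g)
            return (ga.reshape(a.shape), gb.reshape(b.shape))

        out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: (g * (1.0 - t**2),)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: (g * e,)
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: (g * s,)
        return out

    def pow_const(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1.0),)
        return out

    def sqrt(self):
        return self.pow_const(0.5)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def gather_rows(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=int)
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            gr = np.zeros_like(self.data)
            np.add.at(gr, idx, g)
            return (gr,)

        out._backward = bw
        return out

    def softmax(self, axis: int = -1, mask: np.ndarray | None = None):
        """Softmax along ``axis``; positions where ``mask`` is False get
        zero probability (a fully masked slice yields zeros)."""
        x = self.data.copy()
        if mask is not None:
            x = np.where(mask, x, -np.inf)
        mx = np.max(x, axis=axis, keepdims=True)
        mx = np.where(np.isfinite(mx), mx, 0.0)  # fully masked slice
        e = np.exp(x - mx)
        denom = e.sum(axis=axis, keepdims=True)
        denom = np.where(denom == 0.0, 1.0, denom)
        y = e / denom
        out = Tensor(y, parents=(self,))

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        out._backward = bw
        return out

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._backward(t.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None

    def item(self) -> float:
        return float(self.data)


def segment_sum(values: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``values`` into ``n_segments`` buckets given per-row ids."""
    segments = np.asarray(segments, dtype=int)
    shape = (n_segments,) + values.data.shape[1:]
    acc = np.zeros(shape)
    np.add.at(acc, segments, values.data)
    out = Tensor(acc, parents=(values,))
    out._backward = lambda g: (g[segments],)
    return out


def segment_softmax(scores: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a score vector within each segment (for edge attention)."""
    segments = np.asarray(segments, dtype=int)
    # stop-gradient per-segment max for numerical stability
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, segments, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    shifted = scores - Tensor(seg_max[segments])
    e = shifted.exp()
    denom = segment_sum(e, segments, n_segments)
    return e / denom.gather_rows(segments)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = bw
    return out
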