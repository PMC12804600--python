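"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the decoder architectures need: broadcasting
arithmetic, batched matmul, reductions, slicing/advanced indexing,
concatenation, the usual nonlinearities, fused (log-)softmax and dropout.
Gradients accumulate into ``Tensor.grad``; ``backward()`` runs a topological
sweep from the calling tensor (typically a scalar loss).
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape of the broadcast operand."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._prev = ()

    # ------------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self):
        topo, seen = [], set()

        def build(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        import sys
        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 100000))
        try:
            build(self)
        finally:
            sys.setrecursionlimit(limit)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t)

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)

        def back(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        return self._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return self._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def back(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def back(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -out.grad * self.data / other.data**2, other.shape))

        return self._make(self.data / other.data, (self, other), back)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        def back(out):
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), back)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def back(out):
            g = out.grad
            if self.requires_grad:
                gb = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(gb, self.shape))
            if other.requires_grad:
                ga = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(ga, other.shape))

        return self._make(self.data @ other.data, (self, other), back)

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def back(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shapes
    def reshape(self, *shape):
        old = self.shape

        def back(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), back)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), back)

    def __getitem__(self, key):
        def back(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accum(g)

        return self._make(self.data[key], (self,), back)

    # --------------------------------------------------------- nonlinearity
    def exp(self):
        val = np.exp(self.data)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * val)

        return self._make(val, (self,), back)

    def log(self):
        def back(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return self._make(np.log(self.data), (self,), back)

    def sqrt(self):
        val = np.sqrt(self.data)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * 0.5 / val)

        return self._make(val, (self,), back)

    def tanh(self):
        val = np.tanh(self.data)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * (1.0 - val**2))

        return self._make(val, (self,), back)

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * val * (1.0 - val))

        return self._make(val, (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return self._make(self.data * mask, (self,), back)

    # ---------------------------------------------------------------- fused
    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        val = z - lse
        sm = np.exp(val)

        def back(out):
            if self.requires_grad:
                g = out.grad
                self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return self._make(val, (self,), back)

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        val = e / e.sum(axis=axis, keepdims=True)

        def back(out):
            if self.requires_grad:
                g = out.grad
                dot = (g * val).sum(axis=axis, keepdims=True)
                self._accum(val * (g - dot))

        return self._make(val, (self,), back)

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        if not training or p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)

        def back(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return self._make(self.data * mask, (self,), back)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(out):
        pieces = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(g)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = back
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of (B, C) logits against integer targets."""
    ls = logits.log_softmax(axis=-1)
    picked = ls[np.arange(len(targets)), np.asarray(targets, dtype=int)]
    return -picked.mean()


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - _as_tensor(target)
    return (diff * diff).mean()
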