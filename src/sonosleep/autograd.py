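"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the staging network needs: broadcasting
arithmetic, (batched) matmul, elementwise nonlinearities, reductions,
reshape/transpose, fancy indexing with scatter-add backward, and a
gradient-reversal op for adversarial domain adaptation. Everything is
float64 and deterministic.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float32:  # float32 passes through, rest promotes
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

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
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- helpers -----------------------------------------------------------

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

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast_matmul(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast_matmul(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- elementwise -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.maximum(self.data, lo), (self,), bw)

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % self.data.ndim for a in axes))
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), bw)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast_matmul(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce matmul gradient over broadcast batch dimensions."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax in range(grad.ndim - 2):
        if shape[ax] == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


# -- composite ops ---------------------------------------------------------


def logsumexp(x: Tensor, axis: int) -> Tensor:
    m = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant shift
    return (x - m).exp().sum(axis=axis, keepdims=True).log() + m


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return (x - logsumexp(x, axis)).exp()


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    return x - logsumexp(x, axis)


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Identity forward; multiplies the gradient by -lam on the way back."""

    def bw(g):
        if x.requires_grad:
            x._accum(-lam * g)

    return Tensor._make(x.data, (x,), bw)
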