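"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph networks need: dense linear
algebra, elementwise nonlinearities, segment (scatter/gather) operations
for message passing over ragged graph batches, and a batched
matrix-vector product for edge-conditioned convolutions.  Everything is
float64 and purely NumPy, so results are bit-reproducible given a seed
and independent of thread count.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "gather", "segment_sum", "segment_mean", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- coercion ------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-out.grad * self.data / other.data**2, other.data.shape))

        out._backward = _backward
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = _backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = _backward
        return out

    # -- elementwise ---------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _backward
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * 0.5 / out.data)

        out._backward = _backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _backward
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, slope))

        out._backward = _backward
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = _backward
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the bounds."""
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))

        def _backward():
            if self.requires_grad:
                inside = (self.data >= lo) & (self.data <= hi)
                self._accum(out.grad * inside)

        out._backward = _backward
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = _backward
        return out


# -- graph / segment operations -----------------------------------------

def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row-gather x[idx]; gradient is a scatter-add."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], _prev=(x,))

    def _backward():
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, idx, out.grad)
            x._accum(g)

    out._backward = _backward
    return out


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of x into `num_segments` buckets; gradient is a gather."""
    segments = np.asarray(segments, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segments, x.data)
    out = Tensor(data, _prev=(x,))

    def _backward():
        if x.requires_grad:
            x._accum(out.grad[segments])

    out._backward = _backward
    return out


def segment_mean(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    counts = np.bincount(np.asarray(segments, dtype=np.intp), minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    shape = (num_segments,) + (1,) * (x.data.ndim - 1)
    return segment_sum(x, segments, num_segments) * Tensor(1.0 / counts.reshape(shape))


def segment_softmax(logits: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax within each segment along axis 0 (numerically stable).

    `logits` may be 1-D (one score per row) or 2-D (e.g. one per head)."""
    segments = np.asarray(segments, dtype=np.intp)
    # per-segment max as a constant shift (its gradient contribution is zero)
    seg_max = np.full((num_segments,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, segments, logits.data)
    shifted = logits - Tensor(seg_max[segments])
    e = shifted.exp()
    denom = gather(segment_sum(e, segments, num_segments), segments)
    return e / denom


def bmm(theta: Tensor, vec: Tensor) -> Tensor:
    """Batched matrix-vector product: (E, o, i) × (E, i) → (E, o)."""
    out = Tensor(np.einsum("eoi,ei->eo", theta.data, vec.data), _prev=(theta, vec))

    def _backward():
        if theta.requires_grad:
            theta._accum(np.einsum("eo,ei->eoi", out.grad, vec.data))
        if vec.requires_grad:
            vec._accum(np.einsum("eo,eoi->ei", out.grad, theta.data))

    out._backward = _backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
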