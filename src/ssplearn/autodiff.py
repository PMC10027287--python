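"""Compact reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the encoder towers, GRU and training losses
need: broadcasting arithmetic, (batched) matmul, the usual nonlinearities,
reductions, reshaping, concatenation, fancy indexing (for embedding lookup)
and a fused softmax.  Gradients are accumulated by topological traversal of
the recorded graph; `no_grad()` disables graph recording for cheap inference.

All arrays are float64: the model sizes used here are small enough that the
Python-level graph overhead, not FLOPs, dominates, and double precision keeps
finite-difference checks tight.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple = ()
        self._grad_owned = False  # True once .grad is a private writable buffer

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        """A view of the same values, severed from the graph."""
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # grads may be shared views; copy-on-write keeps accumulation safe
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    def _own_grad_buffer(self) -> np.ndarray:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
            self._grad_owned = True
        elif not self._grad_owned:
            self.grad = self.grad.copy()
            self._grad_owned = True
        return self.grad

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_owned = False

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- elementwise -------------------------------------------------------------
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    if isinstance(exponent, Tensor):
        raise TypeError("only scalar exponents are supported")
    data = a.data ** exponent

    def backward(g):
        if a.requires_grad:
            a._accum(g * exponent * a.data ** (exponent - 1.0))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * 0.5 / data)

    return _make(data, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (1.0 - data * data))

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accum(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is zero outside [lo, hi] (straight-through inside)."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(data, (a,), backward)


# -- linear algebra ----------------------------------------------------------
def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            if b.data.ndim == 1:
                ga = np.multiply.outer(g, b.data) if g.ndim else g * b.data
            else:
                ga = np.matmul(g[..., None] if a.data.ndim == 1 and g.ndim == a.data.ndim - 1 else g,
                               np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga.reshape(a.data.shape) if ga.shape != a.data.shape and ga.size == a.data.size else ga,
                                  a.data.shape))
        if b.requires_grad:
            if a.data.ndim == 1:
                gb = np.multiply.outer(a.data, g)
            else:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb.reshape(b.data.shape) if gb.shape != b.data.shape and gb.size == b.data.size else gb,
                                  b.data.shape))

    return _make(data, (a, b), backward)


# -- reductions --------------------------------------------------------------
def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g2, a.data.shape))

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else (
        np.prod([a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# -- shape manipulation ------------------------------------------------------
def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return _make(data, tuple(tensors), backward)


def _is_basic_index(idx) -> bool:
    parts = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(p, (int, np.integer, slice)) or p is Ellipsis for p in parts)


def take(a, idx) -> Tensor:
    """Indexing / gather; integer-array indices make this an embedding lookup.

    The gradient is accumulated in place into the parent's buffer: basic
    (slice) indexing hits no duplicate elements, fancy integer indexing uses
    ``np.add.at``.
    """
    a = as_tensor(a)
    data = a.data[idx]
    basic = _is_basic_index(idx)

    def backward(g):
        if a.requires_grad:
            buf = a._own_grad_buffer()
            if basic:
                buf[idx] += g
            else:
                np.add.at(buf, idx, g)

    return _make(data, (a,), backward)


# -- fused ops ---------------------------------------------------------------
def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accum(data * (g - dot))

    return _make(data, (a,), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask))


def parameter(data: np.ndarray) -> Tensor:
    t = Tensor(data)
    t.requires_grad = True  # parameters require grad even inside no_grad scopes
    return t


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
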