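"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Every mathematical function in this module dispatches on its inputs: with
plain ``numpy`` arrays it computes values only; as soon as a :class:`Tensor`
is involved it records the operation so gradients can be propagated with
:meth:`Tensor.backward`. This lets the encoder/GCN/classifier code be
written once and exercised both as pure numerics (for oracle tests) and as
a trainable computation graph.

Gradient correctness is validated against central finite differences in
the test suite.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

ArrayLike = "np.ndarray | Tensor | float"


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep numpy from broadcasting over Tensor operands; binary ops with
    # ndarrays must fall back to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def value(x) -> np.ndarray:
    """The underlying numpy value of a Tensor, or ``x`` itself."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


def _wrap(a) -> Tensor:
    return a if isinstance(a, Tensor) else Tensor(a)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b):
    if not _is_tensor(a, b):
        return value(a) + value(b)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def mul(a, b):
    if not _is_tensor(a, b):
        return value(a) * value(b)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def matmul(a, b):
    if not _is_tensor(a, b):
        return value(a) @ value(b)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            ga = g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = a.data.T @ g if a.data.ndim == 2 else np.outer(a.data, g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = bw
    return out


def _sigmoid_np(v: np.ndarray) -> np.ndarray:
    # saturated exponentials overflow harmlessly to the correct limit
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-v))


def sigmoid(x):
    if not _is_tensor(x):
        return _sigmoid_np(value(x))
    y = _sigmoid_np(x.data)
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))

    out._backward = bw
    return out


def tanh(x):
    if not _is_tensor(x):
        return np.tanh(value(x))
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - y * y))

    out._backward = bw
    return out


def leaky_relu(x, negative_slope: float = 0.01):
    if not _is_tensor(x):
        v = value(x)
        return np.where(v > 0, v, negative_slope * v)
    y = np.where(x.data > 0, x.data, negative_slope * x.data)
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * np.where(x.data > 0, 1.0, negative_slope))

    out._backward = bw
    return out


def identity(x):
    return x


def concat(parts: Sequence, axis: int = 0):
    if not _is_tensor(*parts):
        return np.concatenate([value(p) for p in parts], axis=axis)
    parts = [_wrap(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]

    def bw(g):
        start = 0
        for p, s in zip(parts, sizes):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                p._accumulate(g[tuple(sl)])
            start += s

    out._backward = bw
    return out


def stack(parts: Sequence):
    """Stack 1-D vectors into a matrix (axis 0)."""
    if not _is_tensor(*parts):
        return np.stack([value(p) for p in parts])
    parts = [_wrap(p) for p in parts]
    out = Tensor(np.stack([p.data for p in parts]), parents=tuple(parts))

    def bw(g):
        for i, p in enumerate(parts):
            if p.requires_grad:
                p._accumulate(g[i])

    out._backward = bw
    return out


def gather_rows(x, indices):
    """Select rows ``x[indices]`` with gradient scatter-add on backward."""
    idx = np.asarray(indices, dtype=np.intp)
    if not _is_tensor(x):
        return value(x)[idx]
    out = Tensor(x.data[idx], parents=(x,))

    def bw(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            x._accumulate(acc)

    out._backward = bw
    return out


def vsum(x):
    """Sum of all elements, as a scalar."""
    if not _is_tensor(x):
        return float(np.sum(value(x)))
    out = Tensor(np.sum(x.data), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    out._backward = bw
    return out


def bilinear_logits(e_left, w, e_right):
    """Pairwise bilinear logits ``z[p, r] = e_left[p]·W[r]·e_right[p]``.

    ``e_left``/``e_right`` are (p, d); ``w`` is (k, d, d); result is (p, k).
    """
    if not _is_tensor(e_left, w, e_right):
        return np.einsum("pa,rab,pb->pr", value(e_left), value(w), value(e_right))
    e_left, w, e_right = _wrap(e_left), _wrap(w), _wrap(e_right)
    z = np.einsum("pa,rab,pb->pr", e_left.data, w.data, e_right.data)
    out = Tensor(z, parents=(e_left, w, e_right))

    def bw(g):
        if e_left.requires_grad:
            e_left._accumulate(np.einsum("pr,rab,pb->pa", g, w.data, e_right.data))
        if w.requires_grad:
            w._accumulate(np.einsum("pr,pa,pb->rab", g, e_left.data, e_right.data))
        if e_right.requires_grad:
            e_right._accumulate(np.einsum("pr,rab,pa->pb", g, w.data, e_left.data))

    out._backward = bw
    return out


def log_softmax(z):
    """Row-wise log-softmax, stabilized with log-sum-exp."""
    v = value(z)
    m = v.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(v - m).sum(axis=-1, keepdims=True))
    if not _is_tensor(z):
        return v - lse
    y = v - lse
    out = Tensor(y, parents=(z,))

    def bw(g):
        if z.requires_grad:
            p = np.exp(y)
            z._accumulate(g - p * g.sum(axis=-1, keepdims=True))

    out._backward = bw
    return out


def softmax(z):
    v = value(z)
    m = v.max(axis=-1, keepdims=True)
    e = np.exp(v - m)
    p = e / e.sum(axis=-1, keepdims=True)
    if not _is_tensor(z):
        return p
    out = Tensor(p, parents=(z,))

    def bw(g):
        if z.requires_grad:
            z._accumulate(p * (g - (g * p).sum(axis=-1, keepdims=True)))

    out._backward = bw
    return out


def cross_entropy(logits, labels):
    """Summed negative log-likelihood of integer ``labels`` under row-wise
    softmax of ``logits`` (log-sum-exp stabilized; never a raw log of 0)."""
    labels = np.asarray(labels, dtype=np.intp)
    ls = log_softmax(logits)
    picked = value(ls)[np.arange(len(labels)), labels]
    if not _is_tensor(logits):
        return float(-picked.sum())
    out = Tensor(-picked.sum(), parents=(ls,))

    def bw(g):
        if ls.requires_grad:
            gg = np.zeros_like(ls.data)
            gg[np.arange(len(labels)), labels] = -float(g)
            ls._accumulate(gg)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# parameter utilities
# ---------------------------------------------------------------------------

def parameter(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int | None = None) -> Tensor:
    """A trainable tensor with symmetric-uniform fan-in scaled initialization."""
    if fan_in is None:
        fan_in = shape[0] if shape else 1
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def zeros_parameter(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def clip_gradients(params: Iterable[Tensor], max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


class SGD:
    """Stochastic gradient descent with optional momentum."""

    def __init__(self, params: Sequence[Tensor], lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            if self.momentum:
                v *= self.momentum
                v -= self.lr * p.grad
                p.data += v
            else:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
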