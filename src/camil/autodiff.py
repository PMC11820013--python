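"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The attention model is small (a handful of affine maps, two softmax
attention blocks and an attention-pooling head), so rather than pulling in
a deep-learning framework the package carries a compact tape-based autodiff
engine supporting exactly the operations the model needs: matmul,
broadcasting add/mul, elementwise nonlinearities, reductions, concatenation
and a numerically stable softplus for the bag-level cross-entropy.

All tensors are float64.  Gradients are accumulated on leaves flagged with
``requires_grad``; :meth:`Tensor.backward` runs a topological sweep of the
tape.  Intermediate nodes keep their gradients after ``backward`` (used by
the Grad-CAM style attribution in :mod:`camil.interpret`).
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union["Tensor", np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node on the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _parents: Tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- tape ------------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            stack = [node]
            order = []
            while stack:
                n = stack.pop()
                if id(n) in seen:
                    continue
                seen.add(id(n))
                order.append(n)
                stack.extend(n._parents)
            # order is a DFS pre-order; we need reverse-topological, which
            # a second pass with dependency counting provides
            topo.extend(order)

        visit(self)
        # Kahn-style ordering: process a node only once all consumers done.
        consumers: dict[int, int] = {}
        for n in topo:
            for p in n._parents:
                consumers[id(p)] = consumers.get(id(p), 0) + 1
        self._accum(grad)
        ready = [self]
        while ready:
            node = ready.pop()
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            for p in node._parents:
                consumers[id(p)] -= 1
                if consumers[id(p)] == 0:
                    ready.append(p)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        return transpose(self)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators -------------------------------------------------------
    def __add__(self, other: ArrayLike) -> "Tensor":
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other: ArrayLike) -> "Tensor":
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return mul(self, -1.0)

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return add(_ensure(other), mul(self, -1.0))

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        return div(self, other)

    def __matmul__(self, other: ArrayLike) -> "Tensor":
        return matmul(self, other)


def _ensure(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitive operations -----------------------------------------------


def add(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out_data = a.data + b.data

    def bwd(g: np.ndarray) -> None:
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def mul(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out_data = a.data * b.data

    def bwd(g: np.ndarray) -> None:
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def div(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out_data = a.data / b.data

    def bwd(g: np.ndarray) -> None:
        a._accum(_unbroadcast(g / b.data, a.data.shape))
        b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def matmul(a: ArrayLike, b: ArrayLike) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out_data = a.data @ b.data

    def bwd(g: np.ndarray) -> None:
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def transpose(a: ArrayLike) -> Tensor:
    a = _ensure(a)

    def bwd(g: np.ndarray) -> None:
        a._accum(g.T)

    return Tensor(a.data.T, _parents=(a,), _backward=bwd)


def relu(a: ArrayLike) -> Tensor:
    a = _ensure(a)
    mask = a.data > 0

    def bwd(g: np.ndarray) -> None:
        a._accum(g * mask)

    return Tensor(a.data * mask, _parents=(a,), _backward=bwd)


def tanh(a: ArrayLike) -> Tensor:
    a = _ensure(a)
    out_data = np.tanh(a.data)

    def bwd(g: np.ndarray) -> None:
        a._accum(g * (1.0 - out_data**2))

    return Tensor(out_data, _parents=(a,), _backward=bwd)


def exp(a: ArrayLike) -> Tensor:
    a = _ensure(a)
    out_data = np.exp(a.data)

    def bwd(g: np.ndarray) -> None:
        a._accum(g * out_data)

    return Tensor(out_data, _parents=(a,), _backward=bwd)


def log(a: ArrayLike) -> Tensor:
    a = _ensure(a)

    def bwd(g: np.ndarray) -> None:
        a._accum(g / a.data)

    return Tensor(np.log(a.data), _parents=(a,), _backward=bwd)


def softplus(a: ArrayLike) -> Tensor:
    """log(1 + e^x), stabilized as max(x, 0) + log1p(e^{-|x|})."""
    a = _ensure(a)
    x = a.data
    out_data = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    sig = 1.0 / (1.0 + np.exp(-x))

    def bwd(g: np.ndarray) -> None:
        a._accum(g * sig)

    return Tensor(out_data, _parents=(a,), _backward=bwd)


def tsum(a: ArrayLike, axis: Optional[int] = None, keepdims: bool = False) -> Tensor:
    a = _ensure(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g: np.ndarray) -> None:
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape))
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(np.broadcast_to(gg, a.data.shape))

    return Tensor(out_data, _parents=(a,), _backward=bwd)


def concat(tensors: Sequence[ArrayLike], axis: int = 1) -> Tensor:
    ts = [_ensure(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum(sizes)[:-1]

    def bwd(g: np.ndarray) -> None:
        for t, piece in zip(ts, np.split(g, offsets, axis=axis)):
            t._accum(piece)

    return Tensor(out_data, _parents=tuple(ts), _backward=bwd)


def softmax_columns(logits: ArrayLike) -> Tensor:
    """Column-wise softmax (each column sums to 1), max-stabilized.

    The per-column max is treated as a constant; softmax is invariant to
    per-column shifts, so this leaves both value and gradient exact.
    """
    logits = _ensure(logits)
    shift = logits.data.max(axis=0, keepdims=True)
    e = exp(logits - shift)
    return div(e, tsum(e, axis=0, keepdims=True))


def softmax_rows(logits: ArrayLike) -> Tensor:
    """Row-wise softmax, max-stabilized (used for instance pooling weights)."""
    logits = _ensure(logits)
    shift = logits.data.max(axis=1, keepdims=True) if logits.data.ndim > 1 else logits.data.max()
    e = exp(logits - shift)
    axis = 1 if logits.data.ndim > 1 else 0
    return div(e, tsum(e, axis=axis, keepdims=True))
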