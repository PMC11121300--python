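"""Compact reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order, accumulating gradients.  The op set is exactly what the
affinity model needs: broadcasting arithmetic, matmul, sparse-dense matmul
with a constant sparse matrix, the sigmoid/tanh/ReLU nonlinearities,
row/column slicing and concatenation, softmax, reductions, and a segmented
max for graph readout.

Gradients are only tracked while :func:`grad_enabled` is true (see
:func:`no_grad`), and only for tensors that (transitively) depend on a
tensor created with ``requires_grad=True``.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Context manager disabling tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = (
        "data", "grad", "requires_grad", "_parents", "_backward", "name",
        "fixed_rows",
    )

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self.name = name
        self.fixed_rows: tuple[int, ...] | None = None  # rows an optimizer must not update

    # -- construction of derived tensors -------------------------------

    @staticmethod
    def _make(
        data: np.ndarray,
        parents: Sequence["Tensor"],
        backward: Callable[[np.ndarray], None],
    ) -> "Tensor":
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                if other.ndim == 2:
                    self._accumulate(g @ other.data.T)
                elif self.ndim == 2:  # (m,n) @ (n,) -> (m,)
                    self._accumulate(np.outer(g, other.data))
                else:  # dot product
                    self._accumulate(g * other.data)
            if other.requires_grad:
                if self.ndim == 2:
                    other._accumulate(self.data.T @ g)
                elif other.ndim == 2:  # (n,) @ (n,k) -> (k,)
                    other._accumulate(np.outer(self.data, g))
                else:
                    other._accumulate(g * self.data)

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities -------------------------------------------------

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            self._accumulate(g * (self.data > 0))

        return Tensor._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- reductions & shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accumulate(g.reshape(self.shape))

        return Tensor._make(out_data, (self,), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g):
            self._accumulate(g.T)

        return Tensor._make(self.data.T, (self,), backward)

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        out_data = self.data[:, start:stop]

        def backward(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        indices = np.asarray(indices, dtype=np.int64)
        out_data = self.data[indices]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, indices, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (one node per timestep)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph as we go
                if node is not self and not node._is_leaf():
                    node.grad = None
                node._backward = None
                node._parents = ()

    def _is_leaf(self) -> bool:
        return self._backward is None and self._parents == ()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis if axis >= 0 else g.ndim + axis] = slice(a, b)
            t._accumulate(g[tuple(idx)])

    return Tensor._make(out_data, tensors, backward)


def spmm(matrix, x: Tensor) -> Tensor:
    """Multiply a constant (sparse or dense) matrix by a tensor: out = A @ x."""
    out_data = np.asarray(matrix @ x.data)

    def backward(g):
        x._accumulate(np.asarray(matrix.T @ g))

    return Tensor._make(out_data, (x,), backward)


def segment_max(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise max within each segment (graph readout).

    ``segment_ids`` assigns each row of ``x`` to a segment; every segment
    must be non-empty.  Gradients flow to the argmax row per (segment,
    feature), first occurrence winning ties.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    n, d = x.data.shape
    out_data = np.full((num_segments, d), -np.inf)
    np.maximum.at(out_data, segment_ids, x.data)
    if np.isinf(out_data).any():
        raise ValueError("segment_max: every segment must contain at least one row")
    # first row attaining the max per segment/feature
    is_max = x.data == out_data[segment_ids]
    row_order = np.arange(n)[:, None]
    order_masked = np.where(is_max, row_order, n)
    pick = np.full((num_segments, d), n, dtype=np.int64)
    np.minimum.at(pick, segment_ids, order_masked)

    def backward(g):
        full = np.zeros_like(x.data)
        cols = np.broadcast_to(np.arange(d), (num_segments, d))
        full[pick.ravel(), cols.ravel()] += g.ravel()
        x._accumulate(full)

    return Tensor._make(out_data, (x,), backward)
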