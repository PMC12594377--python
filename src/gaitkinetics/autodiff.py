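"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains recurrent and graph-convolutional networks on CPU, so it
carries its own small tape-based autodiff engine rather than depending on a
deep-learning framework.  The engine supports exactly the operations the
models need: broadcast arithmetic, (batched) matrix products, the usual
pointwise nonlinearities, reductions, shape manipulation, concatenation and
slicing.  Gradients are accumulated in float64.

Design notes
------------
* A :class:`Tensor` wraps an ``ndarray`` and records its parents and a
  backward closure.  ``Tensor.backward()`` runs a topological sort of the
  recorded graph and accumulates ``grad`` arrays on every node that requires
  gradients.
* Broadcasting is handled generically: every backward closure reduces the
  incoming gradient back onto the parent's shape via :func:`_unbroadcast`.
* There is no in-place mutation of tracked tensors; optimizers update the
  underlying ``.data`` buffers between graph constructions.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an autodiff tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug helper
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward() on a non-differentiable tensor")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    # -- nonlinearities ------------------------------------------------
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g * s * (1.0 - s))

        return Tensor(s, _parents=(self,), _backward=bwd)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g * (1.0 - t * t))

        return Tensor(t, _parents=(self,), _backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g * e)

        return Tensor(e, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g * 0.5 / np.maximum(r, 1e-300))

        return Tensor(r, _parents=(self,), _backward=bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g: np.ndarray) -> None:
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        return Tensor(s, _parents=(self,), _backward=bwd)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            gg = g
            if not keepdims:
                for ax in sorted(a % self.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g.reshape(old_shape))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bwd)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor(np.swapaxes(self.data, a, b), _parents=(self,), _backward=bwd)

    def flip(self, axis: int) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            self._accumulate(np.flip(g, axis=axis))

        return Tensor(np.flip(self.data, axis=axis), _parents=(self,), _backward=bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bwd(g: np.ndarray) -> None:
            # write the slice gradient in place; a fresh zeros buffer per
            # slice would dominate the cost of long unrolled recurrences
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad[idx] += g

        return Tensor(out_data, _parents=(self,), _backward=bwd)


class Parameter(Tensor):
    """A trainable tensor.  ``trainable`` can be cleared to freeze it."""

    __slots__ = ("trainable",)

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.trainable = True


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    ax = axis % out_data.ndim
    sizes = [t.shape[ax] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(start, stop)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    ax = axis % out_data.ndim

    def bwd(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=ax))

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)
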