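"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the classifier needs: dense matmul,
broadcasting add/mul, ReLU, (log-)softmax, concatenation, reductions,
elementwise log/power, per-row gathering, dropout, and a gradient-reversal
op whose forward pass is the identity and whose backward pass multiplies the
incoming gradient by -lambda.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        o = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            o._accumulate(_unbroadcast(g, o.shape))

        return self._make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * o.data, self.shape))
            o._accumulate(_unbroadcast(g * self.data, o.shape))

        return self._make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        return self * o.powi(-1.0)

    def powi(self, p: float) -> "Tensor":
        """Elementwise power with a constant exponent."""

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        return self._make(self.data ** p, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), bw)

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other) -> "Tensor":
        o = self._wrap(other)

        def bw(g):
            self._accumulate(g @ o.data.T)
            o._accumulate(self.data.T @ g)

        return self._make(self.data @ o.data, (self, o), bw)

    __matmul__ = matmul

    @property
    def T(self) -> "Tensor":
        def bw(g):
            self._accumulate(g.T)

        return self._make(self.data.T, (self,), bw)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accumulate(piece)

        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
        if any(t.requires_grad or t._parents for t in tensors):
            out.requires_grad = True
            out._parents = tuple(tensors)
            out._backward = bw
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """out[i] = self[i, index[i]] for a 2-D tensor."""
        index = np.asarray(index, dtype=np.int64)
        rows = np.arange(self.shape[0])

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (rows, index), g)
            self._accumulate(full)

        return self._make(self.data[rows, index], (self,), bw)

    # -- nonlinear normalizers --------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))

        return self._make(y, (self,), bw)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse

        def bw(g):
            self._accumulate(g - np.exp(y) * g.sum(axis=axis, keepdims=True))

        return self._make(y, (self,), bw)

    # -- special -----------------------------------------------------------

    def grad_reverse(self, lam: float) -> "Tensor":
        """Identity forward; backward multiplies the gradient by -lam."""

        def bw(g):
            self._accumulate(-lam * g)

        return self._make(self.data.copy(), (self,), bw)

    def dropout(self, rate: float, rng: np.random.Generator,
                training: bool = True) -> "Tensor":
        if not training or rate <= 0:
            return self
        keep = 1.0 - rate
        mask = (rng.random(self.shape) < keep) / keep

        def bw(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"
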