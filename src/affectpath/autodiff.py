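"""A minimal vectorized reverse-mode automatic differentiation engine.

Tensors wrap float64 numpy arrays and record the operation graph as they
are combined; :meth:`Tensor.backward` walks the tape in reverse
topological order and accumulates gradients into every tensor with
``requires_grad``.  The op set is exactly what the sequence model needs:
broadcasting arithmetic, (batched) matmul, elementwise nonlinearities,
reductions, reshaping, slicing and concatenation.

Gradient correctness is established by central finite differences in the
test suite; everything downstream (attention, LSTM, the training loop)
relies on this module rather than hand-derived layer gradients.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcasting introduced."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"],
            backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        if not t.requires_grad:
            return
        if t.grad is None:
            t.grad = np.zeros_like(t.data)
        t.grad += g

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        a, b = self, Tensor._coerce(other)

        def bwd(g):
            Tensor._accum(a, _unbroadcast(g, a.shape))
            Tensor._accum(b, _unbroadcast(g, b.shape))

        return Tensor._op(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def bwd(g):
            Tensor._accum(a, -g)

        return Tensor._op(-a.data, (a,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        a, b = self, Tensor._coerce(other)

        def bwd(g):
            Tensor._accum(a, _unbroadcast(g * b.data, a.shape))
            Tensor._accum(b, _unbroadcast(g * a.data, b.shape))

        return Tensor._op(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        a, b = self, Tensor._coerce(other)

        def bwd(g):
            Tensor._accum(a, _unbroadcast(g / b.data, a.shape))
            Tensor._accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._op(a.data / b.data, (a, b), bwd)

    def __pow__(self, p: float) -> "Tensor":
        a = self

        def bwd(g):
            Tensor._accum(a, g * p * a.data ** (p - 1))

        return Tensor._op(a.data ** p, (a,), bwd)

    def __matmul__(self, other) -> "Tensor":
        a, b = self, Tensor._coerce(other)

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            Tensor._accum(a, _unbroadcast(ga, a.shape))
            Tensor._accum(b, _unbroadcast(gb, b.shape))

        return Tensor._op(a.data @ b.data, (a, b), bwd)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            Tensor._accum(a, g * out_data)

        return Tensor._op(out_data, (a,), bwd)

    def log(self) -> "Tensor":
        a = self

        def bwd(g):
            Tensor._accum(a, g / a.data)

        return Tensor._op(np.log(a.data), (a,), bwd)

    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            Tensor._accum(a, g * (1.0 - out_data ** 2))

        return Tensor._op(out_data, (a,), bwd)

    def sigmoid(self) -> "Tensor":
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            Tensor._accum(a, g * out_data * (1.0 - out_data))

        return Tensor._op(out_data, (a,), bwd)

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def bwd(g):
            Tensor._accum(a, g * mask)

        return Tensor._op(a.data * mask, (a,), bwd)

    # -- reductions / shaping --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            Tensor._accum(a, np.broadcast_to(gg, a.shape).copy())

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        a = self

        def bwd(g):
            Tensor._accum(a, g.reshape(a.shape))

        return Tensor._op(a.data.reshape(*shape), (a,), bwd)

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        a = self

        def bwd(g):
            Tensor._accum(a, np.swapaxes(g, ax1, ax2))

        return Tensor._op(np.swapaxes(a.data, ax1, ax2), (a,), bwd)

    def __getitem__(self, key) -> "Tensor":
        a = self

        def bwd(g):
            if not a.requires_grad:
                return
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            Tensor._accum(a, full)

        return Tensor._op(a.data[key], (a,), bwd)

    # -- autodiff -----------------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate d(self)/d(leaf) into every requires_grad tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis (differentiable)."""
    parts = [Tensor._coerce(t) for t in tensors]
    sizes = [p.data.shape[axis] for p in parts]

    def bwd(g):
        offset = 0
        for p, s in zip(parts, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(offset, offset + s)
            Tensor._accum(p, g[tuple(sl)])
            offset += s

    return Tensor._op(np.concatenate([p.data for p in parts], axis=axis), parts, bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    parts = [Tensor._coerce(t) for t in tensors]

    def bwd(g):
        for k, p in enumerate(parts):
            Tensor._accum(p, np.take(g, k, axis=axis))

    return Tensor._op(np.stack([p.data for p in parts], axis=axis), parts, bwd)
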