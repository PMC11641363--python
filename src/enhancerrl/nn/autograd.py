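"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine supports exactly the operations the sequence models in this
package need: broadcasting arithmetic, (batched) matmul, strided 1-D
convolution via an im2col lowering, embedding lookup, reductions,
reshaping and the elementwise nonlinearities.  Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward`, which walks the tape in
reverse topological order.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(parents)
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        # Never mutate in place: incoming arrays may be shared between nodes.
        if not self.requires_grad:
            return
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        a = self
        return self._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accum(g * exponent * a.data ** (exponent - 1))

        return self._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return self._make(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return self._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return self._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def relu(self):
        a = self
        mask = a.data > 0
        return self._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return self._make(out_data, (a,),
                          lambda g: a._accum(g * out_data * (1.0 - out_data)))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclamped."""
        a = self
        mask = (a.data > lo) & (a.data < hi)
        return self._make(np.clip(a.data, lo, hi), (a,),
                          lambda g: a._accum(g * mask))

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return self._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return self._make(a.data.reshape(shape), (a,),
                          lambda g: a._accum(g.reshape(a.shape)))

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._make(a.data.transpose(axes), (a,),
                          lambda g: a._accum(g.transpose(inv)))

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._make(a.data[idx], (a,), backward)

    # -- backprop driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- graph-level functions ----------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(data, tensors, backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)

    def backward(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.shape[1]))
            weight._accum(full)

    return Tensor._make(weight.data[ids], (weight,), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           padding: int = 0) -> Tensor:
    """1-D convolution. x: (B, Cin, L); w: (Cout, Cin, K); b: (Cout,)."""
    B, Ci, L = x.shape
    Co, _, K = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    Lp = xp.shape[2]
    Lo = (Lp - K) // stride + 1
    if Lo < 1:
        raise ValueError(
            f"sequence length {L} too short for kernel {K} with stride "
            f"{stride} and padding {padding}")
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)
    cols = cols[:, :, ::stride, :]                       # (B, Ci, Lo, K)
    cols2 = cols.transpose(0, 2, 1, 3).reshape(B * Lo, Ci * K)
    w2 = w.data.reshape(Co, Ci * K)
    out = (cols2 @ w2.T).reshape(B, Lo, Co).transpose(0, 2, 1) + b.data[:, None]

    def backward(g):
        go = g.transpose(0, 2, 1).reshape(B * Lo, Co)    # (B*Lo, Co)
        if b.requires_grad:
            b._accum(go.sum(axis=0))
        if w.requires_grad:
            w._accum((go.T @ cols2).reshape(Co, Ci, K))
        if x.requires_grad:
            gcols = (go @ w2).reshape(B, Lo, Ci, K).transpose(0, 2, 1, 3)
            gxp = np.zeros((B, Ci, Lp))
            for k in range(K):
                gxp[:, :, k:k + Lo * stride:stride] += gcols[:, :, :, k]
            if padding:
                gxp = gxp[:, :, padding:Lp - padding]
            x._accum(gxp)

    return Tensor._make(out, (x, w, b), backward)


def softmax(x: Tensor, axis: int = -1,
            bias: np.ndarray | None = None) -> Tensor:
    """Fused softmax with an optional additive (constant) logit bias.

    Implemented as one primitive so the large attention-score
    intermediates are not materialised per elementwise op.
    """
    z = x.data if bias is None else x.data + bias
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        x._accum((g - (g * y).sum(axis=axis, keepdims=True)) * y)

    return Tensor._make(y, (x,), backward)
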