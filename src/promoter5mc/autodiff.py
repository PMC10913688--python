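"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an ndarray,
records the operations applied to it, and :meth:`Tensor.backward` walks the
tape in reverse topological order accumulating gradients.  Only the
operations the network needs are implemented (elementwise arithmetic,
matmul, 2-D convolution and average pooling, reductions, softmax and the
usual activations), each with a vectorised backward rule.

Parameters are float64 by default; a model may cast itself to float32 and
the ops preserve that dtype. Gradients for broadcast operands are summed
back down to the operand's shape.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "no_grad", "concat", "conv2d", "avg_pool2d"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (evaluation mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    """Floating arrays keep their dtype (float32 models stay float32);
    everything else becomes float64."""
    arr = np.asarray(x)
    if arr.dtype.kind != "f":
        arr = arr.astype(np.float64)
    return arr


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helper ------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd driver ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    # -- elementwise arithmetic --------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _coerce_like(self, x) -> "Tensor":
        """Coerce ``x``; bare python scalars adopt this tensor's dtype so a
        float32 graph is not silently promoted to float64."""
        if isinstance(x, Tensor):
            return x
        if np.isscalar(x):
            return Tensor(np.asarray(x, dtype=self.data.dtype))
        return Tensor(x)

    def __add__(self, other):
        other = self._coerce_like(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce_like(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._op(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce_like(other))

    def __rsub__(self, other):
        return self._coerce_like(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce_like(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._op(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce_like(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor._op(a.data ** e, (a,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._op(a.data @ b.data, (a, b), backward)

    # -- activations ---------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._op(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._op(np.log(a.data), (a,), backward)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._op(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = expit(a.data)

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._op(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._op(np.where(mask, a.data, 0.0), (a,), backward)

    def clamp_min(self, lo: float):
        a = self
        mask = a.data >= lo

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._op(np.maximum(a.data, lo), (a,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                ga = np.broadcast_to(g, a.data.shape)
            else:
                ga = g if keepdims else np.expand_dims(g, axis)
                ga = np.broadcast_to(ga, a.data.shape)
            a._accumulate(ga.copy())

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = math.prod(self.data.shape[ax] for ax in axes)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims: bool = False):
        """Max over ``axis``; ties share the gradient equally."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = a.data == out_data
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            gk = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(mask * (gk / counts))

        result = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._op(result, (a,), backward)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            a._accumulate(y * (g - dot))

        return Tensor._op(y, (a,), backward)

    # -- shape manipulation --------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self

        def backward(g):
            a._accumulate(g.reshape(a.data.shape))

        return Tensor._op(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accumulate(g.transpose(inv))

        return Tensor._op(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            ga = np.zeros_like(a.data)
            np.add.at(ga, key, g)
            a._accumulate(ga)

        return Tensor._op(a.data[key], (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: tuple[int, int] = (0, 0)) -> Tensor:
    """Stride-1 2-D cross-correlation.

    ``x``: (N, C, H, W); ``w``: (F, C, kh, kw); ``b``: (F,) or None.
    ``padding`` is symmetric zero-padding (ph, pw).
    """
    x = Tensor._coerce(x)
    w = Tensor._coerce(w)
    ph, pw = padding
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    if c2 != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = h + 2 * ph - kh + 1
    wo = wd + 2 * pw - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d: kernel larger than padded input")
    # im2col: one matmul instead of kh*kw slice products
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    xcol = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    wmat = w.data.reshape(f, c * kh * kw)
    out = (wmat @ xcol).reshape(n, f, ho, wo)
    parents = [x, w]
    if b is not None:
        b = Tensor._coerce(b)
        out = out + b.data[None, :, None, None]
        parents.append(b)

    def backward(g):
        gmat = g.reshape(n, f, ho * wo)
        if x.requires_grad:
            gxcol = np.tensordot(gmat, wmat, axes=([1], [0]))  # (N, ho*wo, C*kh*kw)
            gxcol = gxcol.transpose(0, 2, 1).reshape(n, c, kh, kw, ho, wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + ho, j:j + wo] += gxcol[:, :, i, j]
            if ph or pw:
                gxp = gxp[:, :, ph:ph + h, pw:pw + wd]
            x._accumulate(gxp)
        if w.requires_grad:
            gw = np.tensordot(gmat, xcol, axes=([0, 2], [0, 2]))  # (F, C*kh*kw)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._op(out, parents, backward)


def avg_pool2d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    """Ceiling-mode average pooling; edge windows average only existing cells.

    A constant map therefore pools to the same constant. Requires
    ``kernel == stride`` (non-overlapping windows).
    """
    if kernel != stride:
        raise ValueError("avg_pool2d supports kernel == stride only")
    x = Tensor._coerce(x)
    n, c, h, w = x.data.shape
    ho = -(-h // stride)
    wo = -(-w // stride)
    out = np.zeros((n, c, ho, wo))
    cnt = np.zeros((ho, wo))
    for i in range(kernel):
        for j in range(kernel):
            xs = x.data[:, :, i::stride, j::stride]
            ha, wb = xs.shape[2], xs.shape[3]
            out[:, :, :ha, :wb] += xs
            cnt[:ha, :wb] += 1
    out /= cnt

    def backward(g):
        gn = g / cnt
        gx = np.zeros_like(x.data)
        for i in range(kernel):
            for j in range(kernel):
                ha = len(range(i, h, stride))
                wb = len(range(j, w, stride))
                gx[:, :, i::stride, j::stride] += gn[:, :, :ha, :wb]
        x._accumulate(gx)

    return Tensor._op(out, (x,), backward)
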