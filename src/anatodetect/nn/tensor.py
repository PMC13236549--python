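"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small define-by-run engine: each operation records its parents
and a closure computing parent gradients.  Arrays keep whatever float dtype
they are given (float32 in normal use; float64 in numerical gradient checks).
Graph recording can be suspended with :func:`no_grad`, which makes inference
allocation-free apart from the forward activations themselves.
"""

from __future__ import annotations

import contextlib
from itertools import product
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_float(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- bookkeeping ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._op(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._op(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._op(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._op(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accum(g * p * np.power(a.data, p - 1))

        return Tensor._op(np.power(a.data, p), (a,), bw)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.shape))

        return Tensor._op(np.matmul(a.data, b.data), (a, b), bw)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return Tensor._op(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._op(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g / (2.0 * out_data))

        return Tensor._op(out_data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._op(a.data * mask, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = _stable_sigmoid(a.data)

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._op(out_data, (a,), bw)

    def softplus(self):
        """log(1 + e^x), computed stably; gradient is sigmoid(x)."""
        a = self
        x = a.data
        out_data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))

        def bw(g):
            a._accum(g * _stable_sigmoid(x))

        return Tensor._op(out_data, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - out_data * out_data))

        return Tensor._op(out_data, (a,), bw)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        a = self
        c = np.sqrt(2.0 / np.pi).astype(a.data.dtype) if False else np.sqrt(2.0 / np.pi)
        x = a.data
        u = c * (x + 0.044715 * x**3)
        t = np.tanh(u)
        out_data = 0.5 * x * (1.0 + t)

        def bw(g):
            du = c * (1.0 + 3 * 0.044715 * x * x)
            a._accum(g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du))

        return Tensor._op(out_data, (a,), bw)

    def maximum(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        mask = a.data >= b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * mask, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~mask), b.shape))

        return Tensor._op(np.maximum(a.data, b.data), (a, b), bw)

    def minimum(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        mask = a.data <= b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * mask, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~mask), b.shape))

        return Tensor._op(np.minimum(a.data, b.data), (a, b), bw)

    def clamp_min(self, v: float):
        return self.maximum(Tensor(np.asarray(v, dtype=self.data.dtype)))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy() if np.ndim(g) else np.full(a.shape, g, dtype=a.data.dtype))
                return
            gg = g
            if not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for ax in sorted(ax % a.ndim for ax in axes):
                    gg = np.expand_dims(gg, ax)
            a._accum(np.broadcast_to(gg, a.shape).astype(a.data.dtype))

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

        return Tensor._op(out_data, (a,), bw)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self

        def bw(g):
            a._accum(g.reshape(a.shape))

        return Tensor._op(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return Tensor._op(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            z = np.zeros(a.shape, dtype=a.data.dtype)
            z[idx] += g  # basic (non-repeating) indexing only
            a._accum(z)

        return Tensor._op(a.data[idx], (a,), bw)

    def roll(self, shift, axis):
        a = self
        shifts = (shift,) if isinstance(shift, int) else tuple(shift)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)

        def bw(g):
            a._accum(np.roll(g, [-s for s in shifts], axis=axes))

        return Tensor._op(np.roll(a.data, shifts, axis=axes), (a,), bw)


# -- free functions -----------------------------------------------------------


def pad(x: Tensor, pad_width) -> Tensor:
    """Zero-padding; ``pad_width`` as for :func:`numpy.pad`."""
    a = Tensor.as_tensor(x)
    pw = [(int(l), int(r)) for l, r in pad_width]

    def bw(g):
        sl = tuple(slice(l, g.shape[i] - r if r else None) for i, (l, r) in enumerate(pw))
        a._accum(g[sl])

    return Tensor._op(np.pad(a.data, pw), (a,), bw)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._op(np.concatenate([t.data for t in ts], axis=axis), ts, bw)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor.as_tensor(t) for t in tensors]

    def bw(g):
        parts = np.moveaxis(g, axis, 0)
        for t, p in zip(ts, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._op(np.stack([t.data for t in ts], axis=axis), ts, bw)


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of an (N, C, D, H, W) tensor."""
    a = x
    n, c, d, h, w = a.shape
    f = factor
    out_data = a.data
    for ax in (2, 3, 4):
        out_data = np.repeat(out_data, f, axis=ax)

    def bw(g):
        gg = g.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))
        a._accum(gg)

    return Tensor._op(out_data, (a,), bw)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int | tuple = 1, padding: int | tuple = 0) -> Tensor:
    """3D cross-correlation: x (N,Cin,D,H,W) * w (Cout,Cin,kd,kh,kw)."""
    x = Tensor.as_tensor(x)
    w = Tensor.as_tensor(w)
    sd, sh, sw = (stride,) * 3 if isinstance(stride, int) else tuple(stride)
    pd, ph, pw = (padding,) * 3 if isinstance(padding, int) else tuple(padding)
    n, cin, _, _, _ = x.shape
    cout, cin_w, kd, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"input channels {cin} != weight channels {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw))) \
        if (pd or ph or pw) else x.data
    dp, hp, wp = xp.shape[2:]
    do = (dp - kd) // sd + 1
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    out_data = np.zeros((n, cout, do, ho, wo), dtype=x.data.dtype)
    for i, j, k in product(range(kd), range(kh), range(kw)):
        xs = xp[:, :, i:i + do * sd:sd, j:j + ho * sh:sh, k:k + wo * sw:sw]
        out_data += np.einsum("ncdhw,oc->nodhw", xs, w.data[:, :, i, j, k],
                              optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        for i, j, k in product(range(kd), range(kh), range(kw)):
            sl = (slice(None), slice(None),
                  slice(i, i + do * sd, sd), slice(j, j + ho * sh, sh),
                  slice(k, k + wo * sw, sw))
            if w.requires_grad:
                dw[:, :, i, j, k] = np.einsum("nodhw,ncdhw->oc", g, xp[sl],
                                              optimize=True)
            if x.requires_grad:
                dxp[sl] += np.einsum("nodhw,oc->ncdhw", g, w.data[:, :, i, j, k],
                                     optimize=True)
        if x.requires_grad:
            dx = dxp[:, :, pd:dp - pd, ph:hp - ph, pw:wp - pw] \
                if (pd or ph or pw) else dxp
            x._accum(dx)
        if w.requires_grad:
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._op(out_data, parents, bw)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     factor: int = 2) -> Tensor:
    """Transposed conv with kernel == stride == factor (non-overlapping).

    x (N,Cin,D,H,W), w (Cin,Cout,f,f,f) -> (N,Cout,D*f,H*f,W*f).
    """
    x = Tensor.as_tensor(x)
    w = Tensor.as_tensor(w)
    f = factor
    n, cin, d, h, wd = x.shape
    cin_w, cout = w.shape[:2]
    if cin != cin_w:
        raise ValueError(f"input channels {cin} != weight channels {cin_w}")
    out_data = np.zeros((n, cout, d * f, h * f, wd * f), dtype=x.data.dtype)
    for i, j, k in product(range(f), repeat=3):
        out_data[:, :, i::f, j::f, k::f] = np.einsum(
            "ncdhw,co->nodhw", x.data, w.data[:, :, i, j, k], optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        for i, j, k in product(range(f), repeat=3):
            gs = g[:, :, i::f, j::f, k::f]
            if x.requires_grad:
                dx += np.einsum("nodhw,co->ncdhw", gs, w.data[:, :, i, j, k],
                                optimize=True)
            if w.requires_grad:
                dw[:, :, i, j, k] = np.einsum("ncdhw,nodhw->co", x.data, gs,
                                              optimize=True)
        if x.requires_grad:
            x._accum(dx)
        if w.requires_grad:
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._op(out_data, parents, bw)
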