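"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives the adversarial network needs:
broadcast arithmetic, reductions, rectifiers, Tanh, strided 2-D
convolution (im2col), zero-insertion dilation and padding (from which
transposed convolution is composed), 2x2 max pooling, and a numerically
stable binary cross-entropy on logits.  Gradients flow through a tape of
:class:`Tensor` nodes; ``backward()`` runs a topological sweep.

This exists because the runtime environment provides no deep-learning
framework; the engine is deliberately small and every primitive is
checked against finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "mul",
    "scale",
    "reciprocal",
    "tsum",
    "tmean",
    "tabs",
    "relu",
    "leaky_relu",
    "tanh",
    "conv2d",
    "dilate2d",
    "pad2d",
    "maxpool2d",
    "concat_channels",
    "bce_with_logits",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape construction (inference / buffered samples)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g, float)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # convenience operators -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        if isinstance(other, Tensor):
            return mul(self, other)
        return scale(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return scale(self, -1.0)

    def __sub__(self, other):
        return add(self, -other if isinstance(other, Tensor) else Tensor(-np.asarray(other)))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward):
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(grad, shape):
    """Sum a broadcast gradient back down to ``shape``."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic


def add(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(data, (a, b), backward)


def scale(a, s: float):
    a = _wrap(a)
    s = float(s)

    def backward(g):
        a._accumulate(g * s)

    return _node(a.data * s, (a,), backward)


def reciprocal(a):
    a = _wrap(a)
    data = 1.0 / a.data

    def backward(g):
        a._accumulate(-g * data * data)

    return _node(data, (a,), backward)


def tsum(a):
    a = _wrap(a)

    def backward(g):
        a._accumulate(np.broadcast_to(g, a.shape).astype(float))

    return _node(a.data.sum(), (a,), backward)


def tmean(a):
    a = _wrap(a)
    n = a.data.size

    def backward(g):
        a._accumulate(np.broadcast_to(g / n, a.shape).astype(float))

    return _node(a.data.mean(), (a,), backward)


def tabs(a):
    a = _wrap(a)
    sign = np.sign(a.data)

    def backward(g):
        a._accumulate(g * sign)

    return _node(np.abs(a.data), (a,), backward)


# ---------------------------------------------------------------------------
# activations


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def leaky_relu(a, slope: float = 0.2):
    a = _wrap(a)
    factor = np.where(a.data > 0, 1.0, slope)

    def backward(g):
        a._accumulate(g * factor)

    return _node(a.data * factor, (a,), backward)


def tanh(a):
    a = _wrap(a)
    data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - data * data))

    return _node(data, (a,), backward)


# ---------------------------------------------------------------------------
# structural ops


def pad2d(a, pad: int):
    """Zero-pad the two trailing axes symmetrically."""
    a = _wrap(a)
    if pad == 0:
        return a
    width = [(0, 0)] * (a.data.ndim - 2) + [(pad, pad), (pad, pad)]
    data = np.pad(a.data, width)

    def backward(g):
        a._accumulate(g[..., pad:-pad, pad:-pad])

    return _node(data, (a,), backward)


def dilate2d(a, stride: int, extra: int = 0):
    """Insert ``stride - 1`` zeros between elements of the trailing axes,
    plus ``extra`` trailing zero rows/columns (output padding)."""
    a = _wrap(a)
    if stride == 1 and extra == 0:
        return a
    h, w = a.shape[-2:]
    oh = (h - 1) * stride + 1 + extra
    ow = (w - 1) * stride + 1 + extra
    data = np.zeros(a.shape[:-2] + (oh, ow))
    data[..., : (h - 1) * stride + 1 : stride, : (w - 1) * stride + 1 : stride] = a.data

    def backward(g):
        a._accumulate(
            g[..., : (h - 1) * stride + 1 : stride, : (w - 1) * stride + 1 : stride]
        )

    return _node(data, (a,), backward)


def _im2col(xp, kh, kw, stride):
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, ho, wo, c * kh * kw
    )
    return cols, ho, wo


def _conv2d_stride1(x, w, b, padding):
    """Shift-and-matmul convolution for unit stride: one (O, C) x (C, HW)
    product per kernel tap, no im2col copy."""
    n, c, h, wdt = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = h + 2 * padding - kh + 1
    wo = wdt + 2 * padding - kw + 1
    out = np.zeros((n, o, ho * wo))
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[:, :, ki : ki + ho, kj : kj + wo].reshape(n, c, ho * wo)
            out += np.matmul(w.data[:, :, ki, kj], xs)
    out = out.reshape(n, o, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gf = g.reshape(n, o, ho * wo)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for ki in range(kh):
                for kj in range(kw):
                    xs = xp[:, :, ki : ki + ho, kj : kj + wo].reshape(n, c, ho * wo)
                    dw[:, :, ki, kj] = np.matmul(gf, xs.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            wt = w.data.transpose(1, 0, 2, 3)  # (C, O, kh, kw)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, :, ki : ki + ho, kj : kj + wo] += np.matmul(
                        wt[:, :, ki, kj], gf
                    ).reshape(n, c, ho, wo)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """2-D cross-correlation, NCHW input, (out, in, kh, kw) weight."""
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    n, c, h, wdt = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
    if stride == 1:
        return _conv2d_stride1(x, w, b, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(o, -1)
    out = cols.reshape(-1, c * kh * kw) @ wmat.T
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols.reshape(-1, c * kh * kw)).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[
                        :, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride
                    ] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def maxpool2d(x, size: int = 2):
    """Non-overlapping max pooling; ties propagate to the first maximum."""
    x = _wrap(x)
    n, c, h, w = x.shape
    if h % size or w % size:
        raise ValueError(f"spatial size {(h, w)} not divisible by pool {size}")
    ho, wo = h // size, w // size
    patches = x.data.reshape(n, c, ho, size, wo, size).transpose(0, 1, 2, 4, 3, 5)
    patches = patches.reshape(n, c, ho, wo, size * size)
    idx = patches.argmax(axis=-1)
    out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dpatch = np.zeros((n, c, ho, wo, size * size))
        np.put_along_axis(dpatch, idx[..., None], g[..., None], axis=-1)
        dx = dpatch.reshape(n, c, ho, wo, size, size).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(n, c, h, w))

    return _node(out, (x,), backward)


def concat_channels(a, b):
    """Concatenate two NCHW tensors along the channel axis."""
    a, b = _wrap(a), _wrap(b)
    ca = a.shape[1]
    data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return _node(data, (a, b), backward)


# ---------------------------------------------------------------------------
# losses


def bce_with_logits(logits, target: float):
    """Mean binary cross-entropy against a constant target in [0, 1],
    computed stably from logits."""
    z = _wrap(logits)
    t = float(target)
    from scipy.special import expit

    data = np.maximum(z.data, 0) - z.data * t + np.log1p(np.exp(-np.abs(z.data)))
    n = z.data.size
    sig = expit(z.data)

    def backward(g):
        z._accumulate(g * (sig - t) / n)

    return _node(data.mean(), (z,), backward)
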