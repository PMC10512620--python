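"""Differentiable operations for :class:`hahnet.nn.Tensor`.

Every function returns a new tensor whose backward closure accumulates
gradients into its parents.  Convolution and pooling are implemented with
``sliding_window_view`` + BLAS matmul (im2col); their backward passes use
strided scatter-adds, so no Python-level per-pixel loops occur anywhere.

Conventions baked in here and relied on elsewhere:

* convolutions support rectangular kernels, strides and (possibly
  asymmetric) zero padding;
* max-pooling pads with ``-inf`` so padding never wins the max;
* average pooling divides by the full window size (padding included);
* batch normalisation uses the biased batch variance both for
  normalisation and for the running-statistics update.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "as_tensor", "add", "sub", "mul", "div", "neg", "pow_", "matmul",
    "sigmoid", "relu", "silu", "exp", "log", "reshape",
    "sum_", "mean_", "amax", "concat",
    "conv2d", "conv1d_same", "maxpool2d", "avgpool2d", "global_avg_pool",
    "batch_norm2d", "linear", "dropout", "cross_entropy", "softmax",
]


# ---------------------------------------------------------------------------
# plumbing

def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _accum(t: Tensor, g: np.ndarray):
    """Accumulate a gradient into ``t``, reducing over broadcast axes."""
    if not t.requires_grad:
        return
    shape = t.data.shape
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    t.grad = g if t.grad is None else t.grad + g


def _out(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _pad_spec(padding):
    """Normalise padding to ((top, bottom), (left, right))."""
    if np.isscalar(padding):
        p = int(padding)
        return (p, p), (p, p)
    a, b = padding
    pa = (a, a) if np.isscalar(a) else tuple(a)
    pb = (b, b) if np.isscalar(b) else tuple(b)
    return pa, pb


# ---------------------------------------------------------------------------
# pointwise & arithmetic

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, g)
        _accum(b, g)

    return _out(a.data + b.data, (a, b), bw)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, g)
        _accum(b, -g)

    return _out(a.data - b.data, (a, b), bw)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _out(a.data * b.data, (a, b), bw)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, g / b.data)
        _accum(b, -g * a.data / (b.data ** 2))

    return _out(a.data / b.data, (a, b), bw)


def neg(a):
    a = as_tensor(a)

    def bw(g):
        _accum(a, -g)

    return _out(-a.data, (a,), bw)


def pow_(a, exponent: float):
    a = as_tensor(a)

    def bw(g):
        _accum(a, g * exponent * a.data ** (exponent - 1))

    return _out(a.data ** exponent, (a,), bw)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _out(a.data @ b.data, (a, b), bw)


def sigmoid(x):
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        _accum(x, g * y * (1.0 - y))

    return _out(y, (x,), bw)


def relu(x):
    x = as_tensor(x)
    mask = x.data > 0

    def bw(g):
        _accum(x, g * mask)

    return _out(np.where(mask, x.data, 0.0), (x,), bw)


def silu(x):
    """x * sigmoid(x) (a.k.a. swish)."""
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    y = x.data * s

    def bw(g):
        _accum(x, g * (s + y * (1.0 - s)))

    return _out(y, (x,), bw)


def exp(x):
    x = as_tensor(x)
    y = np.exp(x.data)

    def bw(g):
        _accum(x, g * y)

    return _out(y, (x,), bw)


def log(x):
    x = as_tensor(x)

    def bw(g):
        _accum(x, g / x.data)

    return _out(np.log(x.data), (x,), bw)


def reshape(x, shape):
    x = as_tensor(x)

    def bw(g):
        _accum(x, g.reshape(x.data.shape))

    return _out(x.data.reshape(shape), (x,), bw)


# ---------------------------------------------------------------------------
# reductions & concatenation

def sum_(x, axis=None, keepdims=False):
    x = as_tensor(x)
    axes = axis if axis is None or isinstance(axis, tuple) else (axis,)

    def bw(g):
        if axes is not None and not keepdims:
            g = np.expand_dims(g, axes)
        _accum(x, np.broadcast_to(g, x.data.shape))

    return _out(x.data.sum(axis=axes, keepdims=keepdims), (x,), bw)


def mean_(x, axis=None, keepdims=False):
    x = as_tensor(x)
    axes = axis if axis is None or isinstance(axis, tuple) else (axis,)
    if axes is None:
        n = x.data.size
    else:
        n = int(np.prod([x.data.shape[a] for a in axes]))

    def bw(g):
        if axes is not None and not keepdims:
            g = np.expand_dims(g, axes)
        _accum(x, np.broadcast_to(g, x.data.shape) / n)

    return _out(x.data.mean(axis=axes, keepdims=keepdims), (x,), bw)


def amax(x, axis, keepdims=False):
    """Max over one axis; ties share the gradient equally."""
    x = as_tensor(x)
    ymax = x.data.max(axis=axis, keepdims=True)
    mask = (x.data == ymax)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        share = mask / mask.sum(axis=axis, keepdims=True)
        _accum(x, g * share)

    y = ymax if keepdims else np.squeeze(ymax, axis=axis)
    return _out(y, (x,), bw)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _out(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


# ---------------------------------------------------------------------------
# convolution & pooling

def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> strided view (N,C,OH,OW,kh,kw)."""
    return sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]


def conv2d(x, w, b=None, stride=1, padding=0):
    """2-D cross-correlation.

    ``x``: (N, C, H, W); ``w``: (O, C, KH, KW); ``b``: (O,) or None.
    ``padding`` may be an int, an (h, w) pair, or ((top,bottom),(left,right)).
    """
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = _pair(stride)
    (pt, pb), (pl, pr) = _pad_spec(padding)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, Ci, KH, KW = wd.shape
    if Ci != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Ci}")
    xp = np.pad(xd, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = _windows(xp, KH, KW, sh, sw)
    OH, OW = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * OH * OW, C * KH * KW)
    wmat = wd.reshape(O, -1)
    y = cols @ wmat.T
    if b is not None:
        b = as_tensor(b)
        y = y + b.data
    y = y.reshape(N, OH, OW, O).transpose(0, 3, 1, 2)

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * OH * OW, O)
        if w.requires_grad:
            _accum(w, (g2.T @ cols).reshape(wd.shape))
        if b is not None and b.requires_grad:
            _accum(b, g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ wmat).reshape(N, OH, OW, C, KH, KW).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(KH):
                for j in range(KW):
                    gxp[:, :, i:i + sh * OH:sh, j:j + sw * OW:sw] += gcols[:, :, :, :, i, j]
            _accum(x, gxp[:, :, pt:pt + H, pl:pl + W])

    parents = (x, w) if b is None else (x, w, b)
    return _out(y, parents, bw)


def conv1d_same(x, w):
    """Single-filter, bias-free 1-D cross-correlation with zero same-padding.

    ``x``: (N, C) — one descriptor vector per sample; ``w``: (k,), k odd.
    Output has shape (N, C).  This is the k-tap cross-channel interaction
    used by efficient channel attention.
    """
    x, w = as_tensor(x), as_tensor(w)
    k = w.data.shape[0]
    if k % 2 == 0:
        raise ValueError("conv1d_same requires an odd kernel size")
    p = k // 2
    N, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (p, p)))
    win = sliding_window_view(xp, k, axis=1)  # (N, C, k)
    y = win @ w.data

    def bw(g):
        if w.requires_grad:
            _accum(w, np.einsum("nck,nc->k", win, g))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, j:j + C] += g * w.data[j]
            _accum(x, gxp[:, p:p + C])

    return _out(y, (x, w), bw)


def maxpool2d(x, kernel, stride=None, padding=0):
    """Max pooling; padded positions hold -inf and never propagate gradient."""
    x = as_tensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    (pt, pb), (pl, pr) = _pad_spec(padding)
    xd = x.data
    N, C, H, W = xd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=-np.inf)
    win = _windows(xp, kh, kw, sh, sw)
    OH, OW = win.shape[2], win.shape[3]
    flat = win.reshape(N, C, OH, OW, kh * kw)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gxp = np.zeros((N, C, H + pt + pb, W + pl + pr), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                sel = (idx == i * kw + j)
                gxp[:, :, i:i + sh * OH:sh, j:j + sw * OW:sw] += g * sel
        _accum(x, gxp[:, :, pt:pt + H, pl:pl + W])

    return _out(y, (x,), bw)


def avgpool2d(x, kernel, stride=None, padding=0):
    """Average pooling with a constant divisor (padding counted)."""
    x = as_tensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    (pt, pb), (pl, pr) = _pad_spec(padding)
    xd = x.data
    N, C, H, W = xd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = _windows(xp, kh, kw, sh, sw)
    OH, OW = win.shape[2], win.shape[3]
    y = win.mean(axis=(-2, -1))
    inv = 1.0 / (kh * kw)

    def bw(g):
        gxp = np.zeros_like(xp)
        gu = g * inv
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + sh * OH:sh, j:j + sw * OW:sw] += gu
        _accum(x, gxp[:, :, pt:pt + H, pl:pl + W])

    return _out(y, (x,), bw)


def global_avg_pool(x):
    """(N, C, H, W) -> (N, C) spatial mean."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    y = x.data.mean(axis=(2, 3))

    def bw(g):
        _accum(x, np.broadcast_to(g[:, :, None, None], x.data.shape) / (H * W))

    return _out(y, (x,), bw)


# ---------------------------------------------------------------------------
# layers

def batch_norm2d(x, gamma, beta, running_mean, running_var, training,
                 momentum=0.1, eps=1e-5):
    """Per-channel batch normalisation over (N, H, W).

    In training mode the biased batch statistics normalise the activations
    and update ``running_mean``/``running_var`` in place; in eval mode the
    running statistics are used and the op is a per-channel affine map.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    xd = x.data
    axes = (0, 2, 3)
    if training:
        mu = xd.mean(axis=axes)
        var = xd.var(axis=axes)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                gx = inv[None, :, None, None] * (
                    gxhat
                    - gxhat.mean(axis=axes, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
                )
            else:
                gx = gxhat * inv[None, :, None, None]
            _accum(x, gx)

    return _out(y, (x, gamma, beta), bw)


def linear(x, w, b=None):
    """x @ w.T + b with ``w``: (out, in)."""
    x, w = as_tensor(x), as_tensor(w)
    y = x.data @ w.data.T
    if b is not None:
        b = as_tensor(b)
        y = y + b.data

    def bw(g):
        _accum(w, g.T @ x.data)
        _accum(x, g @ w.data)
        if b is not None:
            _accum(b, g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _out(y, parents, bw)


def dropout(x, p, training, rng: np.random.Generator):
    """Inverted dropout: at train time keep with prob 1-p and rescale."""
    x = as_tensor(x)
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)

    def bw(g):
        _accum(x, g * keep)

    return _out(x.data * keep, (x,), bw)


def softmax(z: np.ndarray, axis=-1) -> np.ndarray:
    """Plain numpy softmax (no autograd) for probability outputs."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits, targets):
    """Mean softmax cross-entropy; ``targets`` are integer class labels."""
    logits = as_tensor(logits)
    y = np.asarray(targets)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - lse
    n = z.shape[0]
    loss = -logp[np.arange(n), y].mean()

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), y] -= 1.0
        _accum(logits, g * p / n)

    return _out(np.asarray(loss), (logits,), bw)


# ---------------------------------------------------------------------------
# operator sugar on Tensor

def _attach_dunders():
    Tensor.__add__ = lambda self, o: add(self, o)
    Tensor.__radd__ = lambda self, o: add(o, self)
    Tensor.__sub__ = lambda self, o: sub(self, o)
    Tensor.__rsub__ = lambda self, o: sub(o, self)
    Tensor.__mul__ = lambda self, o: mul(self, o)
    Tensor.__rmul__ = lambda self, o: mul(o, self)
    Tensor.__truediv__ = lambda self, o: div(self, o)
    Tensor.__neg__ = lambda self: neg(self)
    Tensor.__pow__ = lambda self, e: pow_(self, e)
    Tensor.__matmul__ = lambda self, o: matmul(self, o)
    Tensor.reshape = lambda self, *shape: reshape(self, shape if len(shape) > 1 else shape[0])


_attach_dunders()
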