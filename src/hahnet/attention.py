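"""Channel and spatial attention blocks (Eca-CBAM).

The attention used throughout the network replaces CBAM's MLP channel
attention (which bottlenecks through a reduced dimension) with efficient
channel attention (ECA): the channel descriptor obtained by global average
pooling is passed through a k-tap 1-D convolution across channels and a
sigmoid, giving one weight per channel without any dimensionality
reduction,

    omega = sigmoid(C1D_k(GAP(x))).

Spatial attention follows CBAM: the channel-wise mean and max maps are
stacked into a 2-plane image, convolved with a single 7x7 filter
(padding 3, no bias) and squashed by a sigmoid,

    Ms = sigmoid(f7x7([AvgPool_c(x); MaxPool_c(x)])),

The composite block applies both multiplicatively, channel attention
first (CBAM's sequential order); the order is overridable.  Because every
attention weight lies strictly in (0, 1), attention can only attenuate:
|output| <= |input| elementwise, and output shape always equals input
shape.

Functional entry points operate on plain numpy arrays (any float dtype);
the ``Module`` classes are what the network assembles.  Non-finite inputs
are rejected with a ``ValueError`` rather than silently propagated.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ShapeError
from .nn import functional as F

__all__ = [
    "eca_kernel_size",
    "eca_channel_attention",
    "spatial_attention",
    "eca_cbam",
    "EcaChannelAttention",
    "SpatialAttention",
    "EcaCbam",
]


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive ECA kernel size: k from C via ``|log2(C)/gamma + b/gamma|``.

    The magnitude is truncated to an integer and bumped to the next odd
    number if even (ECA's convention), so the result is always an odd
    integer >= 1.
    """
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    t = int(abs(np.log2(channels) / gamma + b / gamma))
    k = t if t % 2 == 1 else t + 1
    return max(1, k)


def _check_feature_map(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 4:
        raise ShapeError(f"{name} must be (batch, channel, row, col); got shape {x.shape}")
    if x.shape[1] < 1:
        raise ShapeError(f"{name} must have at least one channel")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values; attention rejects NaN/inf input")
    return x


def eca_channel_attention(x: np.ndarray, weights: np.ndarray):
    """Functional ECA: returns ``(omega, x * omega)``.

    ``x``: (N, C, H, W); ``weights``: 1-D odd-length filter.  ``omega`` has
    shape (N, C) with every entry strictly in (0, 1).
    """
    x = _check_feature_map(x)
    weights = np.asarray(weights)
    if weights.ndim != 1 or weights.shape[0] % 2 == 0:
        raise ValueError("ECA weights must be a 1-D odd-length vector")
    if not np.all(np.isfinite(weights)):
        raise ValueError("ECA weights must be finite")
    t = nn.Tensor(x)
    desc = F.global_avg_pool(t)                 # (N, C)
    omega = F.sigmoid(F.conv1d_same(desc, nn.Tensor(weights)))
    out = x * omega.data[:, :, None, None]
    return omega.data, out


def spatial_attention(x: np.ndarray, conv7_weights: np.ndarray):
    """Functional spatial attention: returns ``(ms, x * ms)``.

    ``conv7_weights`` is the single 7x7 filter over the stacked
    [channel-mean, channel-max] planes, shape (2, 7, 7) (or (1, 2, 7, 7)).
    ``ms`` has shape (N, H, W), entries strictly in (0, 1).
    """
    x = _check_feature_map(x)
    w = np.asarray(conv7_weights)
    if w.ndim == 3:
        w = w[None]
    if w.shape[0] != 1 or w.shape[1] != 2:
        raise ShapeError(f"spatial filter must map 2 planes to 1, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("spatial filter weights must be finite")
    kh, kw = w.shape[2], w.shape[3]
    t = nn.Tensor(x)
    avg = F.mean_(t, axis=1, keepdims=True)
    mx = F.amax(t, axis=1, keepdims=True)
    stacked = F.concat([avg, mx], axis=1)       # (N, 2, H, W)
    ms = F.sigmoid(F.conv2d(stacked, nn.Tensor(w), padding=(kh // 2, kw // 2)))
    out = x * ms.data
    return ms.data[:, 0], out


def eca_cbam(x: np.ndarray, eca_weights: np.ndarray, conv7_weights: np.ndarray,
             order: str = "channel_first") -> np.ndarray:
    """Functional composite attention: channel then spatial (default)."""
    if order not in ("channel_first", "spatial_first"):
        raise ValueError(f"unknown attention order {order!r}")
    if order == "channel_first":
        _, y = eca_channel_attention(x, eca_weights)
        _, y = spatial_attention(y, conv7_weights)
    else:
        _, y = spatial_attention(x, conv7_weights)
        _, y = eca_channel_attention(y, eca_weights)
    return y


class EcaChannelAttention(nn.Module):
    """ECA layer: GAP -> k-tap 1-D conv across channels -> sigmoid -> scale.

    ``kernel_size`` overrides the adaptive rule (gamma=2, b=1) when given.
    """

    def __init__(self, channels: int, kernel_size: int | None = None,
                 gamma: float = 2.0, b: float = 1.0, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel_size is None:
            kernel_size = eca_kernel_size(channels, gamma, b)
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError("ECA kernel size must be odd and >= 1")
        self.channels = channels
        self.kernel_size = kernel_size
        std = 1.0 / np.sqrt(kernel_size)
        self.weight = nn.Parameter(rng.normal(0.0, std, kernel_size).astype(dtype))

    def forward(self, x):
        omega = F.sigmoid(F.conv1d_same(F.global_avg_pool(x), self.weight))
        return F.mul(x, F.reshape(omega, (omega.shape[0], omega.shape[1], 1, 1)))


class SpatialAttention(nn.Module):
    """CBAM spatial attention: [mean_c; max_c] -> 7x7 conv -> sigmoid -> scale."""

    def __init__(self, kernel_size: int = 7, *, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = nn.Conv2d(2, 1, kernel_size, padding=kernel_size // 2,
                              bias=False, rng=rng, dtype=dtype)

    def forward(self, x):
        avg = F.mean_(x, axis=1, keepdims=True)
        mx = F.amax(x, axis=1, keepdims=True)
        ms = F.sigmoid(self.conv(F.concat([avg, mx], axis=1)))
        return F.mul(x, ms)


class EcaCbam(nn.Module):
    """Sequential composition of ECA channel and CBAM spatial attention."""

    def __init__(self, channels: int, kernel_size: int | None = None,
                 spatial_kernel: int = 7, order: str = "channel_first", *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if order not in ("channel_first", "spatial_first"):
            raise ValueError(f"unknown attention order {order!r}")
        self.order = order
        self.channel = EcaChannelAttention(channels, kernel_size, rng=rng, dtype=dtype)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng, dtype=dtype)

    def forward(self, x):
        if self.order == "channel_first":
            return self.spatial(self.channel(x))
        return self.channel(self.spatial(x))
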