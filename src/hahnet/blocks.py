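"""Convolutional building blocks: stem, Inception modules, gated reductions
and the parallel downsampling block.

The multi-scale modules follow the InceptionV3 family layout (the network
is a modified InceptionV3): four parallel lines per block, fused by channel
concatenation.  Two structural changes distinguish this architecture from
plain InceptionV3:

* the reduction modules (InceptionB / InceptionD) gain a fourth line that
  computes a global per-channel gate — global average pooling of the block
  input, a 1x1 convolution mapping to the concatenated channel count, and
  a sigmoid — which multiplies the fused lines before a final SiLU;
* a dedicated ``DownsampleBlock`` (average-pool line + strided-conv line,
  both batch-normalised, concatenated and gated the same way) feeds the
  half-resolution branch of the parallel network.

All channel counts scale by ``width_multiplier`` so reduced-width models
run quickly on a CPU.  Resolution convention: every stride-2 operation in
these blocks pads so the output is ceil(H/2) x ceil(W/2); the stem keeps
the classic InceptionV3 valid-padding schedule (299 -> 35).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ShapeError
from .nn import functional as F

__all__ = [
    "scaled", "BasicConv2d", "Stem",
    "InceptionA", "InceptionB", "InceptionC", "InceptionD", "InceptionE",
    "DownsampleBlock",
]


def scaled(channels: int, width_multiplier: float) -> int:
    """Width-scaled channel count, never below 1."""
    return max(1, int(round(channels * width_multiplier)))


def _ceil_half_pool_pad(h: int, w: int):
    """Asymmetric padding so a 2x2/stride-2 pool yields ceil(H/2) x ceil(W/2)."""
    return (0, h % 2), (0, w % 2)


class BasicConv2d(nn.Module):
    """Conv (bias-free) + batch-norm + ReLU — the unit of every Inception line."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, *, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, stride=stride,
                              padding=padding, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        return F.relu(self.bn(self.conv(x)))


class _GateLine(nn.Module):
    """Global per-channel gate: GAP -> 1x1 conv (with bias) -> sigmoid.

    Returns a vector in (0,1)^out for each sample, broadcast over space by
    the caller.  Zero weights and bias give the 0.5 gate.
    """

    def __init__(self, in_ch, out_ch, *, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 1, bias=True, rng=rng)

    def forward(self, x):
        pooled = F.global_avg_pool(x)                     # (N, C)
        n, c = pooled.shape
        g = F.sigmoid(self.conv(F.reshape(pooled, (n, c, 1, 1))))
        return g                                          # (N, out, 1, 1)


class Stem(nn.Module):
    """Input stem: five convolutions and two max-poolings, 299 -> 35.

    Layout (valid padding except the third conv):
    3x3/2, 3x3, 3x3 pad 1, maxpool 3x3/2, 1x1, 3x3, maxpool 3x3/2.
    Accepts any square input >= 75 px; 299 px yields 35x35 maps.
    """

    MIN_INPUT = 75

    def __init__(self, width_multiplier: float = 1.0, *, rng):
        super().__init__()
        s = lambda c: scaled(c, width_multiplier)
        self.conv1 = BasicConv2d(3, s(32), 3, stride=2, rng=rng)
        self.conv2 = BasicConv2d(s(32), s(32), 3, rng=rng)
        self.conv3 = BasicConv2d(s(32), s(64), 3, padding=1, rng=rng)
        self.conv4 = BasicConv2d(s(64), s(80), 1, rng=rng)
        self.conv5 = BasicConv2d(s(80), s(192), 3, rng=rng)
        self.out_channels = s(192)

    def forward(self, x):
        n, c, h, w = x.shape
        if c != 3:
            raise ShapeError(f"stem expects 3-channel input, got {c}")
        if h < self.MIN_INPUT or w < self.MIN_INPUT:
            raise ShapeError(
                f"stem needs spatial size >= {self.MIN_INPUT}, got {h}x{w}")
        x = self.conv3(self.conv2(self.conv1(x)))
        x = F.maxpool2d(x, 3, stride=2)
        x = self.conv5(self.conv4(x))
        return F.maxpool2d(x, 3, stride=2)


class InceptionA(nn.Module):
    """Stride-1 multi-scale block (1x1 | 5x5 | double 3x3 | avg-pool+1x1)."""

    def __init__(self, in_ch, pool_ch, width_multiplier=1.0, *, rng):
        super().__init__()
        s = lambda c: scaled(c, width_multiplier)
        self.b1 = BasicConv2d(in_ch, s(64), 1, rng=rng)
        self.b5_1 = BasicConv2d(in_ch, s(48), 1, rng=rng)
        self.b5_2 = BasicConv2d(s(48), s(64), 5, padding=2, rng=rng)
        self.b3_1 = BasicConv2d(in_ch, s(64), 1, rng=rng)
        self.b3_2 = BasicConv2d(s(64), s(96), 3, padding=1, rng=rng)
        self.b3_3 = BasicConv2d(s(96), s(96), 3, padding=1, rng=rng)
        self.pool_proj = BasicConv2d(in_ch, pool_ch, 1, rng=rng)
        self.out_channels = s(64) + s(64) + s(96) + pool_ch

    def forward(self, x):
        lines = [
            self.b1(x),
            self.b5_2(self.b5_1(x)),
            self.b3_3(self.b3_2(self.b3_1(x))),
            self.pool_proj(F.avgpool2d(x, 3, stride=1, padding=1)),
        ]
        return F.concat(lines, axis=1)


class InceptionC(nn.Module):
    """Stride-1 factorised-7x7 block (1x1 | 1x7-7x1 | double 7x7 | pool)."""

    def __init__(self, in_ch, c7, width_multiplier=1.0, *, rng):
        super().__init__()
        s = lambda c: scaled(c, width_multiplier)
        c7s = s(c7)
        out = s(192)
        self.b1 = BasicConv2d(in_ch, out, 1, rng=rng)
        self.b7_1 = BasicConv2d(in_ch, c7s, 1, rng=rng)
        self.b7_2 = BasicConv2d(c7s, c7s, (1, 7), padding=(0, 3), rng=rng)
        self.b7_3 = BasicConv2d(c7s, out, (7, 1), padding=(3, 0), rng=rng)
        self.b7d_1 = BasicConv2d(in_ch, c7s, 1, rng=rng)
        self.b7d_2 = BasicConv2d(c7s, c7s, (7, 1), padding=(3, 0), rng=rng)
        self.b7d_3 = BasicConv2d(c7s, c7s, (1, 7), padding=(0, 3), rng=rng)
        self.b7d_4 = BasicConv2d(c7s, c7s, (7, 1), padding=(3, 0), rng=rng)
        self.b7d_5 = BasicConv2d(c7s, out, (1, 7), padding=(0, 3), rng=rng)
        self.pool_proj = BasicConv2d(in_ch, out, 1, rng=rng)
        self.out_channels = 4 * out

    def forward(self, x):
        lines = [
            self.b1(x),
            self.b7_3(self.b7_2(self.b7_1(x))),
            self.b7d_5(self.b7d_4(self.b7d_3(self.b7d_2(self.b7d_1(x))))),
            self.pool_proj(F.avgpool2d(x, 3, stride=1, padding=1)),
        ]
        return F.concat(lines, axis=1)


class InceptionE(nn.Module):
    """Stride-1 expanded block with split 1x3/3x1 branches."""

    def __init__(self, in_ch, width_multiplier=1.0, *, rng):
        super().__init__()
        s = lambda c: scaled(c, width_multiplier)
        self.b1 = BasicConv2d(in_ch, s(320), 1, rng=rng)
        self.b3_1 = BasicConv2d(in_ch, s(384), 1, rng=rng)
        self.b3_2a = BasicConv2d(s(384), s(384), (1, 3), padding=(0, 1), rng=rng)
        self.b3_2b = BasicConv2d(s(384), s(384), (3, 1), padding=(1, 0), rng=rng)
        self.b3d_1 = BasicConv2d(in_ch, s(448), 1, rng=rng)
        self.b3d_2 = BasicConv2d(s(448), s(384), 3, padding=1, rng=rng)
        self.b3d_3a = BasicConv2d(s(384), s(384), (1, 3), padding=(0, 1), rng=rng)
        self.b3d_3b = BasicConv2d(s(384), s(384), (3, 1), padding=(1, 0), rng=rng)
        self.pool_proj = BasicConv2d(in_ch, s(192), 1, rng=rng)
        self.out_channels = s(320) + 4 * s(384) + s(192)

    def forward(self, x):
        a = self.b3_1(x)
        b = self.b3d_2(self.b3d_1(x))
        lines = [
            self.b1(x),
            F.concat([self.b3_2a(a), self.b3_2b(a)], axis=1),
            F.concat([self.b3d_3a(b), self.b3d_3b(b)], axis=1),
            self.pool_proj(F.avgpool2d(x, 3, stride=1, padding=1)),
        ]
        return F.concat(lines, axis=1)


class _GatedReduction(nn.Module):
    """Shared machinery of the modified InceptionB / InceptionD.

    Lines 1-3 (two convolutional paths with a final stride-2 conv, plus a
    stride-2 max-pool path) are concatenated; when ``gated`` the fourth
    line turns the block input into a per-channel gate which multiplies
    the concatenation, followed by SiLU.  When not gated the block is the
    plain InceptionV3 reduction (concatenation only).
    """

    gated: bool

    def __init__(self):
        super().__init__()

    def _finish(self, x, lines):
        fused = F.concat(lines, axis=1)
        if not self.gated:
            return fused
        gate = self.gate(x)
        return F.silu(F.mul(fused, gate))

    def forward(self, x):  # pragma: no cover - overridden line layout
        raise NotImplementedError


class InceptionB(_GatedReduction):
    """First reduction: 17x17-scale entry.  Halves H and W (ceil)."""

    def __init__(self, in_ch, width_multiplier=1.0, gated=True, *, rng):
        super().__init__()
        s = lambda c: scaled(c, width_multiplier)
        self.b3 = BasicConv2d(in_ch, s(384), 3, stride=2, padding=1, rng=rng)
        self.b3d_1 = BasicConv2d(in_ch, s(64), 1, rng=rng)
        self.b3d_2 = BasicConv2d(s(64), s(96), 3, padding=1, rng=rng)
        self.b3d_3 = BasicConv2d(s(96), s(96), 3, stride=2, padding=1, rng=rng)
        self.out_channels = s(384) + s(96) + in_ch
        self.gated = gated
        if gated:
            self.gate = _GateLine(in_ch, self.out_channels, rng=rng)

    def forward(self, x):
        lines = [
            self.b3(x),
            self.b3d_3(self.b3d_2(self.b3d_1(x))),
            F.maxpool2d(x, 3, stride=2, padding=1),
        ]
        return self._finish(x, lines)


class InceptionD(_GatedReduction):
    """Second reduction: 8x8-scale entry.  Halves H and W (ceil)."""

    def __init__(self, in_ch, width_multiplier=1.0, gated=True, *, rng):
        super().__init__()
        s = lambda c: scaled(c, width_multiplier)
        self.b3_1 = BasicConv2d(in_ch, s(192), 1, rng=rng)
        self.b3_2 = BasicConv2d(s(192), s(320), 3, stride=2, padding=1, rng=rng)
        self.b7_1 = BasicConv2d(in_ch, s(192), 1, rng=rng)
        self.b7_2 = BasicConv2d(s(192), s(192), (1, 7), padding=(0, 3), rng=rng)
        self.b7_3 = BasicConv2d(s(192), s(192), (7, 1), padding=(3, 0), rng=rng)
        self.b7_4 = BasicConv2d(s(192), s(192), 3, stride=2, padding=1, rng=rng)
        self.out_channels = s(320) + s(192) + in_ch
        self.gated = gated
        if gated:
            self.gate = _GateLine(in_ch, self.out_channels, rng=rng)

    def forward(self, x):
        lines = [
            self.b3_2(self.b3_1(x)),
            self.b7_4(self.b7_3(self.b7_2(self.b7_1(x)))),
            F.maxpool2d(x, 3, stride=2, padding=1),
        ]
        return self._finish(x, lines)


class DownsampleBlock(nn.Module):
    """Parallel downsampling with a global gate.  Halves H and W (ceil).

    Line 1: 2x2/2 average pool -> 1x1 conv -> batch-norm.
    Line 2: 3x3/2 conv (pad 1) -> batch-norm.
    Lines 1-2 fuse by channel concatenation (``fusion="add"`` sums them
    instead, in which case both lines produce ``out_channels``).
    Line 3: GAP -> 1x1 conv -> sigmoid gate over the fused channels.
    Output: SiLU(fused * gate).
    """

    def __init__(self, in_ch, out_ch=None, fusion="concat", *, rng):
        super().__init__()
        if fusion not in ("concat", "add"):
            raise ValueError(f"unknown fusion mode {fusion!r}")
        out_ch = in_ch if out_ch is None else out_ch
        self.fusion = fusion
        if fusion == "concat":
            c1 = out_ch // 2
            c2 = out_ch - c1
        else:
            c1 = c2 = out_ch
        self.conv1 = nn.Conv2d(in_ch, c1, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(c1)
        self.conv2 = nn.Conv2d(in_ch, c2, 3, stride=2, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c2)
        self.gate = _GateLine(in_ch, out_ch, rng=rng)
        self.out_channels = out_ch

    def forward(self, x):
        n, c, h, w = x.shape
        if h < 2 or w < 2:
            raise ShapeError(f"DownsampleBlock needs spatial dims >= 2, got {h}x{w}")
        pooled = F.avgpool2d(x, 2, stride=2, padding=_ceil_half_pool_pad(h, w))
        line1 = self.bn1(self.conv1(pooled))
        line2 = self.bn2(self.conv2(x))
        if self.fusion == "concat":
            fused = F.concat([line1, line2], axis=1)
        else:
            fused = F.add(line1, line2)
        return F.silu(F.mul(fused, self.gate(x)))
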