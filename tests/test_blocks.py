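"""Contracts of the stem, Inception blocks, gated reductions and the
downsampling block: shapes, gate closed forms, hand-built oracles, gradients."""

import numpy as np
import pytest

from hahnet import blocks
from hahnet.errors import ShapeError
from hahnet.nn import Tensor, functional as F


def rng():
    return np.random.default_rng(31)


def zero_params(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


# ---------------------------------------------------------------------------
# stem

def test_stem_shape_contract_at_299():
    stem = blocks.Stem(width_multiplier=0.125, rng=rng()).eval()
    x = Tensor(np.zeros((2, 3, 299, 299), dtype=np.float32))
    out = stem(x)
    assert out.shape == (2, stem.out_channels, 35, 35)
    assert np.all(np.isfinite(out.data))


def test_stem_rejects_wrong_input():
    stem = blocks.Stem(width_multiplier=0.125, rng=rng())
    with pytest.raises(ShapeError, match="3-channel"):
        stem(Tensor(np.zeros((1, 1, 299, 299), dtype=np.float32)))
    with pytest.raises(ShapeError, match=">= 75"):
        stem(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))


# ---------------------------------------------------------------------------
# stride-1 blocks

@pytest.mark.parametrize("make", [
    lambda r: blocks.InceptionA(16, pool_ch=8, width_multiplier=0.125, rng=r),
    lambda r: blocks.InceptionC(16, c7=128, width_multiplier=0.125, rng=r),
    lambda r: blocks.InceptionE(16, width_multiplier=0.125, rng=r),
])
def test_stride1_blocks_preserve_spatial_and_declare_channels(make):
    block = make(rng()).eval()
    x = Tensor(np.random.default_rng(0).normal(size=(2, 16, 9, 9)).astype(np.float32))
    out = block(x)
    assert out.shape == (2, block.out_channels, 9, 9)


def test_width_multiplier_monotone_in_parameters():
    small = blocks.InceptionA(16, pool_ch=4, width_multiplier=0.25, rng=rng())
    large = blocks.InceptionA(16, pool_ch=4, width_multiplier=1.0, rng=rng())
    assert small.num_parameters() < large.num_parameters()


def test_channel_mismatch_raises():
    block = blocks.InceptionA(16, pool_ch=4, width_multiplier=0.25, rng=rng()).eval()
    with pytest.raises(ValueError, match="channels"):
        block(Tensor(np.zeros((1, 8, 9, 9), dtype=np.float32)))


# ---------------------------------------------------------------------------
# gated reductions

@pytest.mark.parametrize("cls,h,expected", [
    (blocks.InceptionB, 9, 5), (blocks.InceptionB, 8, 4),
    (blocks.InceptionD, 9, 5), (blocks.InceptionD, 8, 4),
])
def test_reductions_ceil_halve_spatial(cls, h, expected):
    block = cls(12, width_multiplier=0.125, rng=rng()).eval()
    x = Tensor(np.random.default_rng(1).normal(size=(1, 12, h, h)).astype(np.float32))
    out = block(x)
    assert out.shape == (1, block.out_channels, expected, expected)


@pytest.mark.parametrize("cls", [blocks.InceptionB, blocks.InceptionD])
def test_zeroed_gate_gives_half_gate_closed_form(cls, monkeypatch):
    r = rng()
    gated = cls(8, width_multiplier=0.125, gated=True, rng=np.random.default_rng(5))
    plain = cls(8, width_multiplier=0.125, gated=False, rng=np.random.default_rng(5))
    # identical line weights; zero only the gate parameters
    plain_names = {n for n, _ in plain.named_parameters()}
    gstate = gated.state_dict()
    plain.load_state_dict({n: gstate[n] for n in plain.state_dict()})
    for name, p in gated.named_parameters():
        if name.startswith("gate."):
            p.data = np.zeros_like(p.data)
    gated.eval(), plain.eval()

    x = Tensor(np.random.default_rng(6).normal(size=(1, 8, 8, 8)).astype(np.float32))
    concat = plain(x).data          # lines 1-3 fused, no gate, no SiLU
    got = gated(x).data
    expected = 0.5 * concat / (1.0 + np.exp(-0.5 * concat))   # SiLU(0.5 * concat)
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_gated_reduction_zero_input_gives_zero_output():
    block = blocks.InceptionB(8, width_multiplier=0.125, rng=rng()).eval()
    out = block(Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32)))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-7)   # SiLU(0) = 0


def test_gate_vector_strictly_in_unit_interval():
    block = blocks.InceptionB(8, width_multiplier=0.125, rng=rng()).eval()
    x = Tensor(np.random.default_rng(2).normal(size=(2, 8, 8, 8)).astype(np.float32))
    g = block.gate(x).data
    assert g.shape == (2, block.out_channels, 1, 1)
    assert np.all((g > 0) & (g < 1))


def test_gated_reduction_matches_compositional_oracle():
    """Tiny gated reduction with fixed weights vs. explicit composition."""
    block = blocks.InceptionB(8, width_multiplier=0.125, rng=np.random.default_rng(7)).eval()
    x = np.random.default_rng(8).normal(size=(1, 8, 8, 8)).astype(np.float32)

    # oracle: run each line separately through the public sub-modules, then
    # compose concat -> gate -> SiLU with plain numpy
    t = Tensor(x)
    l1 = block.b3(t).data
    l2 = block.b3d_3(block.b3d_2(block.b3d_1(t))).data
    l3 = F.maxpool2d(t, 3, stride=2, padding=1).data
    fused = np.concatenate([l1, l2, l3], axis=1)
    desc = x.mean(axis=(2, 3)) @ block.gate.conv.weight.data[:, :, 0, 0].T \
        + block.gate.conv.bias.data
    gate = 1.0 / (1.0 + np.exp(-desc))[:, :, None, None]
    z = fused * gate
    expected = z / (1.0 + np.exp(-z))

    np.testing.assert_allclose(block(t).data, expected, atol=1e-5)


# ---------------------------------------------------------------------------
# DownsampleBlock

@pytest.mark.parametrize("h,expected", [(8, 4), (9, 5), (4, 2), (5, 3)])
def test_downsample_ceil_halves(h, expected):
    block = blocks.DownsampleBlock(6, rng=rng()).eval()
    x = Tensor(np.random.default_rng(3).normal(size=(1, 6, h, h)).astype(np.float32))
    out = block(x)
    assert out.shape == (1, 6, expected, expected)


def test_downsample_rejects_tiny_input():
    block = blocks.DownsampleBlock(6, rng=rng()).eval()
    with pytest.raises(ShapeError, match=">= 2"):
        block(Tensor(np.zeros((1, 6, 1, 1), dtype=np.float32)))


def test_downsample_zero_gate_closed_form():
    block = blocks.DownsampleBlock(6, rng=np.random.default_rng(9)).eval()
    for name, p in block.named_parameters():
        if name.startswith("gate."):
            p.data = np.zeros_like(p.data)
    x = Tensor(np.random.default_rng(10).normal(size=(1, 6, 8, 8)).astype(np.float32))

    # fused lines recomputed through the public sub-modules
    pooled = F.avgpool2d(x, 2, stride=2)
    l1 = block.bn1(block.conv1(pooled)).data
    l2 = block.bn2(block.conv2(x)).data
    fused = np.concatenate([l1, l2], axis=1)
    expected = 0.5 * fused / (1.0 + np.exp(-0.5 * fused))
    np.testing.assert_allclose(block(x).data, expected, atol=1e-6)


def test_downsample_matches_hand_oracle():
    """Fixed-weight 4x4 instance vs. a from-scratch numpy computation
    (explicit average pool, 1x1 / 3x3 convolution, eval-mode batch-norm
    with identity affine parameters, gate and SiLU)."""
    block = blocks.DownsampleBlock(4, rng=np.random.default_rng(11)).eval()
    x = np.random.default_rng(12).normal(size=(1, 4, 4, 4)).astype(np.float64)

    w1 = block.conv1.weight.data.astype(np.float64)     # (2, 4, 1, 1)
    w2 = block.conv2.weight.data.astype(np.float64)     # (2, 4, 3, 3)
    wg = block.gate.conv.weight.data.astype(np.float64)[:, :, 0, 0]
    bg = block.gate.conv.bias.data.astype(np.float64)
    eps = block.bn1.eps

    # line 1: 2x2 stride-2 average pool then 1x1 conv
    pooled = np.zeros((1, 4, 2, 2))
    for c in range(4):
        for i in range(2):
            for j in range(2):
                pooled[0, c, i, j] = x[0, c, 2 * i:2 * i + 2, 2 * j:2 * j + 2].mean()
    l1 = np.einsum("oc,ncij->noij", w1[:, :, 0, 0], pooled)
    # line 2: 3x3 stride-2 conv, pad 1
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    l2 = np.zeros((1, 2, 2, 2))
    for o in range(2):
        for i in range(2):
            for j in range(2):
                patch = xp[0, :, 2 * i:2 * i + 3, 2 * j:2 * j + 3]
                l2[0, o, i, j] = (patch * w2[o]).sum()
    # eval-mode batch-norm with fresh running stats (mean 0, var 1) and
    # identity affine parameters is division by sqrt(1 + eps)
    fused = np.concatenate([l1, l2], axis=1) / np.sqrt(1.0 + eps)
    gate = 1.0 / (1.0 + np.exp(-(x.mean(axis=(2, 3)) @ wg.T + bg)))
    z = fused * gate[:, :, None, None]
    expected = z / (1.0 + np.exp(-z))

    got = block(Tensor(x.astype(np.float32))).data
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_downsample_add_fusion_mode():
    block = blocks.DownsampleBlock(6, out_ch=5, fusion="add", rng=rng()).eval()
    x = Tensor(np.random.default_rng(13).normal(size=(1, 6, 8, 8)).astype(np.float32))
    assert block(x).shape == (1, 5, 4, 4)


# ---------------------------------------------------------------------------
# cross-cutting properties

@pytest.mark.parametrize("make", [
    lambda r: blocks.InceptionA(8, pool_ch=4, width_multiplier=0.125, rng=r),
    lambda r: blocks.InceptionB(8, width_multiplier=0.125, rng=r),
    lambda r: blocks.InceptionD(8, width_multiplier=0.125, rng=r),
    lambda r: blocks.DownsampleBlock(8, rng=r),
])
def test_blocks_backpropagate_finite_nonzero_gradients(make):
    block = make(np.random.default_rng(14))   # training mode
    x = Tensor(np.random.default_rng(15).normal(size=(2, 8, 8, 8)).astype(np.float32),
               requires_grad=True)
    out = block(x)
    F.sum_(F.mul(out, out)).backward()
    assert np.all(np.isfinite(x.grad)) and np.any(x.grad != 0)
    grads = [p.grad for p in block.parameters()]
    assert all(g is not None and np.all(np.isfinite(g)) for g in grads)
    assert any(np.any(g != 0) for g in grads)


def test_parameter_count_deterministic_in_spec():
    a = blocks.InceptionB(12, width_multiplier=0.5, rng=np.random.default_rng(0))
    b = blocks.InceptionB(12, width_multiplier=0.5, rng=np.random.default_rng(99))
    assert a.num_parameters() == b.num_parameters()
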