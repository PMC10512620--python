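"""Full network assembly and ablation variants.

Topology (``variant="full"``): a shared stem (5 convs + 2 max-pools)
feeds two parallel feature-extraction lines that see the image at two
scales — line P1 at stem resolution, line P2 behind a gated
``DownsampleBlock`` at half resolution.  Each line runs the module
sequence

    InceptionA x3 -> Eca-CBAM -> InceptionB -> InceptionC x4
    -> Eca-CBAM -> InceptionD -> InceptionE x2

(attention sits immediately before each reduction), ends in global
average pooling, and the two pooled descriptors are concatenated, passed
through dropout and a single fully connected layer to ``num_classes``
logits (4 HER2 levels: 0, 1+, 2+, 3+).

Ablation variants:

* ``no_downsample_parallel`` — drop the DownsampleBlock and the second
  line; the model becomes serial (P1 only).
* ``unmodified_BD`` — use plain InceptionV3 reduction blocks (no global
  gate line, no SiLU) in both lines.
* ``no_attention`` — strip every Eca-CBAM insertion.

The parallel topology is isolated in :meth:`HAHNet.__init__` so that
alternative wirings are a one-function change.  A seed in
:class:`ModelConfig` fully determines the weights; two models built from
the same config are parameter-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .attention import EcaCbam
from .blocks import (DownsampleBlock, InceptionA, InceptionB, InceptionC,
                     InceptionD, InceptionE, Stem, scaled)
from .errors import ConfigError, ShapeError
from .nn import functional as F

__all__ = ["ModelConfig", "HAHNet", "build_model", "predict_proba", "VARIANTS"]

VARIANTS = ("full", "no_downsample_parallel", "unmodified_BD", "no_attention")

#: synonyms used in ablation tables
VARIANT_ALIASES = {
    "hahnet_1": "no_downsample_parallel",
    "hahnet_2": "unmodified_BD",
    "hahnet_3": "no_attention",
}


@dataclass
class ModelConfig:
    """Everything that determines a constructed network."""

    num_classes: int = 4
    width_multiplier: float = 1.0
    input_size: int = 299
    variant: str = "full"
    dropout_rate: float = 0.5
    seed: int = 0
    a_repeats: int = 3
    c_repeats: int = 4
    e_repeats: int = 2
    attention_order: str = "channel_first"
    downsample_fusion: str = "concat"

    def __post_init__(self):
        variant = VARIANT_ALIASES.get(str(self.variant).lower(), self.variant)
        if variant not in VARIANTS:
            raise ConfigError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS} "
                f"or aliases {tuple(VARIANT_ALIASES)}")
        self.variant = variant
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        if self.input_size < Stem.MIN_INPUT:
            raise ConfigError(
                f"input_size must be >= {Stem.MIN_INPUT} (the stem reduces "
                f"resolution ~8.5x and must not collapse spatial dims)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.width_multiplier <= 0:
            raise ConfigError("width_multiplier must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class _FeatureLine(nn.Module):
    """One feature-extraction line: A*k -> att -> B -> C*k -> att -> D -> E*k -> GAP."""

    def __init__(self, in_ch, cfg: ModelConfig, *, rng):
        super().__init__()
        wm = cfg.width_multiplier
        gated = cfg.variant != "unmodified_BD"
        with_attention = cfg.variant != "no_attention"

        mods = nn.ModuleList()
        ch = in_ch
        pool_features = [32, 64, 64]
        for i in range(cfg.a_repeats):
            pf = scaled(pool_features[min(i, len(pool_features) - 1)], wm)
            block = InceptionA(ch, pool_ch=pf, width_multiplier=wm, rng=rng)
            mods.append(block)
            ch = block.out_channels
        if with_attention:
            mods.append(EcaCbam(ch, order=cfg.attention_order, rng=rng))
        b = InceptionB(ch, width_multiplier=wm, gated=gated, rng=rng)
        mods.append(b)
        ch = b.out_channels
        c7s = [128, 160, 160, 192]
        for i in range(cfg.c_repeats):
            c7 = c7s[min(i, len(c7s) - 1)]
            block = InceptionC(ch, c7=c7, width_multiplier=wm, rng=rng)
            mods.append(block)
            ch = block.out_channels
        if with_attention:
            mods.append(EcaCbam(ch, order=cfg.attention_order, rng=rng))
        d = InceptionD(ch, width_multiplier=wm, gated=gated, rng=rng)
        mods.append(d)
        ch = d.out_channels
        for _ in range(cfg.e_repeats):
            block = InceptionE(ch, width_multiplier=wm, rng=rng)
            mods.append(block)
            ch = block.out_channels
        self.mods = mods
        self.out_features = ch

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return F.global_avg_pool(x)


class HAHNet(nn.Module):
    """The assembled classifier.  See module docstring for the topology."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.stem = Stem(cfg.width_multiplier, rng=rng)
        ch = self.stem.out_channels

        self.line1 = _FeatureLine(ch, cfg, rng=rng)
        features = self.line1.out_features
        if cfg.variant != "no_downsample_parallel":
            self.downsample = DownsampleBlock(ch, fusion=cfg.downsample_fusion, rng=rng)
            self.line2 = _FeatureLine(self.downsample.out_channels, cfg, rng=rng)
            features += self.line2.out_features
        else:
            self.downsample = None
            self.line2 = None

        self.dropout = nn.Dropout(cfg.dropout_rate,
                                  rng=np.random.default_rng(cfg.seed + 1))
        self.fc = nn.Linear(features, cfg.num_classes, rng=rng)

    def forward(self, x) -> nn.Tensor:
        """Batch of tiles (N, 3, input_size, input_size) -> logits (N, num_classes)."""
        x = F.as_tensor(x)
        if x.ndim != 4:
            raise ShapeError(f"expected (batch, 3, H, W), got shape {x.shape}")
        n, c, h, w = x.shape
        expect = self.cfg.input_size
        if h != expect or w != expect:
            raise ShapeError(
                f"expected {expect}x{expect} input, got {h}x{w}")
        feats = self.stem(x)
        pooled = [self.line1(feats)]
        if self.line2 is not None:
            pooled.append(self.line2(self.downsample(feats)))
        merged = pooled[0] if len(pooled) == 1 else F.concat(pooled, axis=1)
        return self.fc(self.dropout(merged))


def build_model(cfg: ModelConfig) -> HAHNet:
    """Deterministically construct a network from its config."""
    return HAHNet(cfg)


def predict_proba(model: HAHNet, batch) -> np.ndarray:
    """Softmax class probabilities, rows summing to 1.  Eval-mode, no grad."""
    was_training = model.training
    model.eval()
    try:
        logits = model(batch).data
    finally:
        model.train(was_training)
    return nn.softmax(logits, axis=1)
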