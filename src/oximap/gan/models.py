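"""Generator and discriminator architectures.

The generator is an encoder–decoder fusion of U-Net and ResNet ideas:
residual blocks of five 3x3 convolutions (with an addition from the
output of the first convolution to the output of the fourth) at each
resolution level, 2x2 max-pool downsampling, 3x3 up-convolutions, long
additive skip connections between matching levels, and a final 3x3
convolution with Tanh.  Encoder activations are plain rectifiers,
decoder activations leaky (slope 0.2).  The discriminator is a patch
classifier — three stride-2 4x4 convolutions followed by two stride-1
layers — whose single-output receptive field is 70x70 pixels at the
default configuration.  All convolutions in both networks are
spectrally normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Conv2d, ConvTranspose2d, Module

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "ResidualBlock",
    "Generator",
    "Discriminator",
    "count_spectral_layers",
]


@dataclass(frozen=True)
class GeneratorConfig:
    levels: int = 4
    widths: Tuple[int, ...] = (64, 128, 256, 512)
    in_channels: int = 3
    out_channels: int = 1
    decoder_slope: float = 0.2
    spectral_norm: bool = True

    def __post_init__(self):
        if len(self.widths) != self.levels:
            raise ValueError("one width per level required")

    @classmethod
    def toy(cls, levels: int = 2, widths: Tuple[int, ...] = (8, 16)) -> "GeneratorConfig":
        """Small configuration that trains in minutes on one CPU core."""
        return cls(levels=levels, widths=widths)

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)


@dataclass(frozen=True)
class DiscriminatorConfig:
    widths: Tuple[int, ...] = (64, 128, 256, 512, 1)
    kernel: int = 4
    strides: Tuple[int, ...] = (2, 2, 2, 1, 1)
    in_channels: int = 4  # 3 conditioning channels + 1 candidate map
    slope: float = 0.2
    spectral_norm: bool = True

    def __post_init__(self):
        if len(self.widths) != len(self.strides):
            raise ValueError("one stride per layer required")

    @classmethod
    def toy(cls) -> "DiscriminatorConfig":
        return cls(widths=(8, 16, 32, 64, 1))

    def layer_spec(self):
        """(kernel, stride) pairs for receptive-field arithmetic."""
        return [(self.kernel, s) for s in self.strides]


class ResidualBlock(Module):
    """Five 3x3 convolutions; the output of the first is added to the
    output of the fourth before the fifth."""

    def __init__(self, in_ch, out_ch, slope, spectral_norm, rng):
        self.slope = slope
        self.convs = [
            Conv2d(in_ch if i == 0 else out_ch, out_ch, 3, padding=1,
                   spectral_norm=spectral_norm, rng=rng)
            for i in range(5)
        ]

    def _act(self, x):
        if self.slope == 0.0:
            return ag.relu(x)
        return ag.leaky_relu(x, self.slope)

    def forward(self, x: Tensor) -> Tensor:
        h1 = self._act(self.convs[0](x))
        h = self._act(self.convs[1](h1))
        h = self._act(self.convs[2](h))
        h4 = self.convs[3](h)
        h = self._act(ag.add(h4, h1))
        return self._act(self.convs[4](h))


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig = GeneratorConfig(), rng=None):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.cfg = cfg
        w = cfg.widths
        sn = cfg.spectral_norm
        self.encoder = [
            ResidualBlock(cfg.in_channels if i == 0 else w[i - 1], w[i], 0.0, sn, rng)
            for i in range(cfg.levels)
        ]
        self.upconvs = [
            ConvTranspose2d(w[i + 1], w[i], spectral_norm=sn, rng=rng)
            for i in range(cfg.levels - 1)
        ]
        self.decoder = [
            ResidualBlock(w[i], w[i], cfg.decoder_slope, sn, rng)
            for i in range(cfg.levels - 1)
        ]
        self.final = Conv2d(w[0], cfg.out_channels, 3, padding=1, spectral_norm=sn, rng=rng)
        self.long_skips = True  # exposed for connectivity probes

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h, wdt = x.shape[-2:]
        d = self.cfg.divisor
        if h % d or wdt % d:
            raise ValueError(f"spatial size {(h, wdt)} not divisible by {d}")
        skips = []
        out = x
        for i, block in enumerate(self.encoder):
            out = block(out)
            if i < self.cfg.levels - 1:
                skips.append(out)
                out = ag.maxpool2d(out, 2)
        for i in range(self.cfg.levels - 2, -1, -1):
            out = self.upconvs[i](out)
            if self.long_skips:
                out = ag.add(out, skips[i])
            out = self.decoder[i](out)
        return ag.tanh(self.final(out))


class Discriminator(Module):
    """Patch classifier over a conditioning input concatenated with a
    candidate saturation map; emits one logit per receptive patch."""

    def __init__(self, cfg: DiscriminatorConfig = DiscriminatorConfig(), rng=None):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.cfg = cfg
        chans = [cfg.in_channels, *cfg.widths]
        self.convs = [
            Conv2d(chans[i], chans[i + 1], cfg.kernel, stride=cfg.strides[i], padding=1,
                   spectral_norm=cfg.spectral_norm, rng=rng)
            for i in range(len(cfg.widths))
        ]

    def forward(self, condition: Tensor, candidate: Tensor) -> Tensor:
        if not isinstance(condition, Tensor):
            condition = Tensor(condition)
        if not isinstance(candidate, Tensor):
            candidate = Tensor(candidate)
        if condition.shape[-2:] != candidate.shape[-2:]:
            raise ValueError("condition/candidate spatial shape mismatch")
        out = ag.concat_channels(condition, candidate)
        last = len(self.convs) - 1
        for i, conv in enumerate(self.convs):
            out = conv(out)
            if i != last:
                out = ag.leaky_relu(out, self.cfg.slope)
        return out


def count_spectral_layers(model: Module):
    """(normalized, total) convolution counts — introspection check that
    spectral normalization covers every convolution."""
    total = 0
    normalized = 0
    for m in model.modules():
        if isinstance(m, (Conv2d, ConvTranspose2d)):
            total += 1
            if m._sn is not None:
                normalized += 1
    return normalized, total
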