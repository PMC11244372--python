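"""Four-stage hierarchical encoder with convolutional attention.

Stage geometry: strides (4, 8, 16, 32), channels (32, 64, 160, 256), block
depths (3, 3, 5, 2), FFN expansion ratios (8, 8, 4, 4).  Each building block
is an attention block followed by a feed-forward block, both residual with
drop-path.  The attention block runs a 5x5 depthwise convolution, three
parallel strip-convolution branches (7, 11, 21) summed with the base, and a
channel mixer producing the attention map that multiplies the block input.
With ``use_s4`` the mixer carries the global S4-2D convolution in place of
the plain 1x1 convolution; switching it off restores the original design so
the two variants differ only in the ``mixer.s4`` parameter block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor
from .s4_2d import S4Layer2D

__all__ = ["EncoderConfig", "PyramidFeatures", "Encoder", "Stem",
           "MSCABlock", "FFNBlock", "encoder_forward"]


@dataclass
class EncoderConfig:
    channels: tuple = (32, 64, 160, 256)
    depths: tuple = (3, 3, 5, 2)
    expansion_ratios: tuple = (8, 8, 4, 4)
    use_s4: bool = True
    state_dim: int = 16
    drop_path_rate: float = 0.01
    bn_epsilon: float = 1e-5
    bn_momentum: float = 0.1
    strip_sizes: tuple = (7, 11, 21)
    dw_kernel: int = 5

    def __post_init__(self):
        lens = {len(self.channels), len(self.depths), len(self.expansion_ratios)}
        if lens != {4}:
            raise ValueError("encoder requires exactly four stages")
        if min(self.channels) < 1 or min(self.depths) < 1 or min(self.expansion_ratios) < 1:
            raise ValueError("all stage counts must be positive")


@dataclass
class PyramidFeatures:
    """The four stage outputs at strides 4, 8, 16, 32 (each (B, C, H, W))."""

    stages: tuple

    def __post_init__(self):
        if len(self.stages) != 4:
            raise ValueError("PyramidFeatures requires four pyramid levels")


class Stem(nn.Module):
    """Two stride-2 3x3 convolutions with normalization: stride 4 at C channels."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        c1 = cfg.channels[0]
        self.conv1 = nn.Conv2d(3, c1 // 2, 3, stride=2, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(c1 // 2, cfg.bn_epsilon, cfg.bn_momentum)
        self.act = nn.GELU()
        self.conv2 = nn.Conv2d(c1 // 2, c1, 3, stride=2, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(c1, cfg.bn_epsilon, cfg.bn_momentum)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 3:
            raise ValueError(f"stem expects 3 input channels, got {x.shape[1]}")
        return self.bn2(self.conv2(self.act(self.bn1(self.conv1(x)))))


class ChannelMixer(nn.Module):
    """The 1x1-convolution slot of the attention block.

    Always contains the pointwise mixing convolution; with ``use_s4`` the
    global S4-2D convolution (which owns that pointwise conv) replaces it.
    """

    def __init__(self, channels: int, use_s4: bool, state_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        if use_s4:
            self.s4 = S4Layer2D(channels, state_dim, rng=rng)
        else:
            self.pointwise = nn.Conv2d(channels, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if hasattr(self, "s4"):
            return self.s4(x)
        return self.pointwise(x)


class MSCABlock(nn.Module):
    """Multi-scale convolutional attention block (residual, drop-path)."""

    def __init__(self, channels: int, cfg: EncoderConfig, rng: np.random.Generator,
                 stage: int = 0, index: int = 0):
        super().__init__()
        C = channels
        k = cfg.dw_kernel
        self.norm = nn.BatchNorm2d(C, cfg.bn_epsilon, cfg.bn_momentum)
        self.dw = nn.Conv2d(C, C, k, padding=k // 2, groups=C, rng=rng)
        self.branches = nn.ModuleList()
        for s in cfg.strip_sizes:
            branch = nn.Sequential(
                nn.Conv2d(C, C, (1, s), padding=(0, s // 2), groups=C, rng=rng),
                nn.Conv2d(C, C, (s, 1), padding=(s // 2, 0), groups=C, rng=rng),
            )
            self.branches.append(branch)
        self.mixer = ChannelMixer(C, cfg.use_s4, cfg.state_dim, rng)
        self.drop_path = nn.DropPath(cfg.drop_path_rate, rng=rng)
        self._where = f"stage {stage} attention block {index}"

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm(x)
        a = self.dw(h)
        acc = a
        for branch in self.branches:
            acc = acc + branch(a)
        attn = self.mixer(acc)
        out = x + self.drop_path(attn * h)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError(f"non-finite activations in {self._where}")
        return out


class FFNBlock(nn.Module):
    """Pointwise expand -> depthwise 3x3 -> GELU -> pointwise project, residual."""

    def __init__(self, channels: int, expansion: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        hidden = channels * expansion
        self.norm = nn.BatchNorm2d(channels, cfg.bn_epsilon, cfg.bn_momentum)
        self.fc1 = nn.Conv2d(channels, hidden, 1, rng=rng)
        self.dw = nn.Conv2d(hidden, hidden, 3, padding=1, groups=hidden, rng=rng)
        self.act = nn.GELU()
        self.fc2 = nn.Conv2d(hidden, channels, 1, rng=rng)
        self.drop_path = nn.DropPath(cfg.drop_path_rate, rng=rng)
        self.hidden_width = hidden

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm(x)
        h = self.fc2(self.act(self.dw(self.fc1(h))))
        return x + self.drop_path(h)


class Downsample(nn.Module):
    """Stride-2 3x3 convolution with normalization between stages."""

    def __init__(self, cin: int, cout: int, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, stride=2, padding=1, rng=rng)
        self.norm = nn.BatchNorm2d(cout, cfg.bn_epsilon, cfg.bn_momentum)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x))


class Stage(nn.Module):
    def __init__(self, index: int, cin: int, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        C = cfg.channels[index]
        self.downsample = Downsample(cin, C, cfg, rng) if index > 0 else None
        self.blocks = nn.ModuleList()
        for b in range(cfg.depths[index]):
            self.blocks.append(_BuildingBlock(C, cfg, rng, stage=index, index=b))

    def forward(self, x: Tensor) -> Tensor:
        if self.downsample is not None:
            x = self.downsample(x)
        for block in self.blocks:
            x = block(x)
        return x


class _BuildingBlock(nn.Module):
    """One attention + FFN building block (the unit the stage depths count)."""

    def __init__(self, channels: int, cfg: EncoderConfig, rng: np.random.Generator,
                 stage: int, index: int):
        super().__init__()
        self.attn = MSCABlock(channels, cfg, rng, stage=stage, index=index)
        self.ffn = FFNBlock(channels, cfg.expansion_ratios[stage], cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.ffn(self.attn(x))


class Encoder(nn.Module):
    def __init__(self, cfg: EncoderConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg or EncoderConfig()
        rng = rng or np.random.default_rng()
        self.stem = Stem(self.cfg, rng)
        self.stages = nn.ModuleList()
        cin = self.cfg.channels[0]
        for i in range(4):
            self.stages.append(Stage(i, cin, self.cfg, rng))
            cin = self.cfg.channels[i]

    def forward(self, x: Tensor) -> PyramidFeatures:
        H, W = x.shape[2], x.shape[3]
        if H % 32 or W % 32:
            raise ValueError(f"encoder input must be stride-32 divisible, got {(H, W)}")
        h = self.stem(x)
        outs = []
        for stage in self.stages:
            h = stage(h)
            outs.append(h)
        return PyramidFeatures(stages=tuple(outs))


def encoder_forward(image: Tensor, cfg: EncoderConfig | None = None,
                    rng: np.random.Generator | None = None) -> PyramidFeatures:
    """Build a fresh encoder and run one forward pass (convenience/tests)."""
    enc = Encoder(cfg, rng).eval()
    return enc(image)
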