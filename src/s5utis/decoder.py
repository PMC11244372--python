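"""UNETR-like decoder: progressive 2x upsampling with skip fusion.

Three up-blocks climb the pyramid (1/32 -> 1/16 -> 1/8 -> 1/4); a final 4x
refinement path (two more 2x blocks fed by shallow convolutions of the input
image) restores full resolution before the 1x1 two-class head.  Decoder
widths mirror the encoder on the way up: 256 -> 160 -> 64 -> 32 -> 16.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat

from .encoder import EncoderConfig, PyramidFeatures

__all__ = ["DecoderConfig", "Logits", "UpBlock", "Decoder", "HamDecoderStub"]


@dataclass
class DecoderConfig:
    skip_channels: tuple = (32, 64, 160, 256)   # encoder stage widths, shallow->deep
    head_channels: int = 16
    num_classes: int = 2
    decoder_kind: str = "unetr"                 # {"unetr", "ham"}
    upsample: str = "transpose"                 # {"transpose", "bilinear"}

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.decoder_kind not in ("unetr", "ham"):
            raise ValueError(f"unknown decoder_kind {self.decoder_kind!r}")
        if self.upsample not in ("transpose", "bilinear"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")


@dataclass
class Logits:
    """Class scores (num_classes, H, W) at the original image resolution."""

    data: np.ndarray


class _Upsample2x(nn.Module):
    def __init__(self, cin: int, cout: int, mode: str, rng: np.random.Generator):
        super().__init__()
        self.mode = mode
        if mode == "transpose":
            self.op = nn.ConvTranspose2d(cin, cout, 2, stride=2, rng=rng)
        else:
            self.op = nn.Conv2d(cin, cout, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "transpose":
            return self.op(x)
        return self.op(F.bilinear_upsample2x(x))


class UpBlock(nn.Module):
    """Upsample deep features 2x, concatenate the skip, fuse residually."""

    def __init__(self, cin: int, cskip: int, cout: int, cfg: DecoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.up = _Upsample2x(cin, cout, cfg.upsample, rng)
        cat = cout + cskip
        self.conv1 = nn.Conv2d(cat, cout, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.act = nn.GELU()
        self.residual = nn.Conv2d(cat, cout, 1, rng=rng)

    def forward(self, deep: Tensor, skip: Tensor) -> Tensor:
        up = self.up(deep)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"up_block spatial mismatch: upsampled {up.shape[2:]} vs skip {skip.shape[2:]}"
            )
        cat = concat([up, skip], axis=1)
        h = self.act(self.bn1(self.conv1(cat)))
        h = self.bn2(self.conv2(h))
        return self.act(h + self.residual(cat))


class HamDecoderStub(nn.Module):
    """Configuration stub for the original lightweight decoder head."""

    def forward(self, feats, image=None):  # pragma: no cover - exercised via raise
        raise NotImplementedError(
            "decoder_kind='ham' is a configuration stub; the shipped decoder is "
            "'unetr'. Instantiate with DecoderConfig(decoder_kind='unetr')."
        )


class Decoder(nn.Module):
    def __init__(self, cfg: DecoderConfig | None = None,
                 encoder_cfg: EncoderConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg or DecoderConfig()
        enc_ch = (encoder_cfg or EncoderConfig()).channels
        if self.cfg.skip_channels != tuple(enc_ch):
            raise ValueError(
                f"decoder skip channels {self.cfg.skip_channels} must align with "
                f"encoder channels {tuple(enc_ch)}"
            )
        rng = rng or np.random.default_rng()
        if self.cfg.decoder_kind == "ham":
            self.ham = HamDecoderStub()
            return
        c1, c2, c3, c4 = self.cfg.skip_channels
        head = self.cfg.head_channels
        self.up3 = UpBlock(c4, c3, c3, self.cfg, rng)      # 1/32 -> 1/16
        self.up2 = UpBlock(c3, c2, c2, self.cfg, rng)      # 1/16 -> 1/8
        self.up1 = UpBlock(c2, c1, c1, self.cfg, rng)      # 1/8  -> 1/4
        # full-resolution refinement fed by shallow image convolutions
        self.img_skip_half = nn.Conv2d(3, head, 3, stride=2, padding=1, rng=rng)
        self.img_skip_full = nn.Conv2d(3, head // 2, 3, padding=1, rng=rng)
        self.up0a = UpBlock(c1, head, head, self.cfg, rng)     # 1/4 -> 1/2
        self.up0b = UpBlock(head, head // 2, head, self.cfg, rng)  # 1/2 -> 1/1
        self.classifier = nn.Conv2d(head, self.cfg.num_classes, 1, rng=rng)

    def forward(self, feats: PyramidFeatures, image: Tensor) -> Tensor:
        if self.cfg.decoder_kind == "ham":
            return self.ham(feats, image)
        f1, f2, f3, f4 = feats.stages
        h = self.up3(f4, f3)
        h = self.up2(h, f2)
        h = self.up1(h, f1)
        h = self.up0a(h, self.img_skip_half(image))
        h = self.up0b(h, self.img_skip_full(image))
        return self.classifier(h)
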