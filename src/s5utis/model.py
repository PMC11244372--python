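"""Full segmentation network: encoder + decoder, padding, inference, checkpoints."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn.tensor import Tensor
from .decoder import Decoder, DecoderConfig, Logits
from .encoder import Encoder, EncoderConfig

__all__ = ["SegmentationModel", "segment", "save_checkpoint", "load_checkpoint",
           "pad_to_stride", "decoder_forward"]


def pad_to_stride(image: np.ndarray, stride: int = 32) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad (C, H, W) so both spatial dims are multiples of ``stride``."""
    C, H, W = image.shape
    ph = (-H) % stride
    pw = (-W) % stride
    if ph or pw:
        image = np.pad(image, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    return image, (H, W)


class SegmentationModel(nn.Module):
    """Encoder-decoder network mapping RGB images to two-class logits."""

    def __init__(self, encoder_cfg: EncoderConfig | None = None,
                 decoder_cfg: DecoderConfig | None = None, seed: int = 0):
        super().__init__()
        self.encoder_cfg = encoder_cfg or EncoderConfig()
        self.decoder_cfg = decoder_cfg or DecoderConfig(
            skip_channels=tuple(self.encoder_cfg.channels)
        )
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(self.encoder_cfg, rng)
        self.decoder = Decoder(self.decoder_cfg, self.encoder_cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        """(B, 3, H, W) -> (B, num_classes, H, W); H, W must be stride-32 multiples."""
        feats = self.encoder(x)
        return self.decoder(feats, x)

    def logits_for_image(self, image: np.ndarray) -> Logits:
        """Run a single (3, H, W) image of arbitrary size; crops padding back."""
        padded, (H, W) = pad_to_stride(np.asarray(image, dtype=np.float32))
        out = self.forward(Tensor(padded[None]))
        return Logits(data=out.data[0, :, :H, :W].astype(float))


def decoder_forward(model: SegmentationModel, image: np.ndarray) -> Logits:
    """Pyramid -> full-resolution logits for one image (inference convenience)."""
    return model.logits_for_image(image)


def refresh_batchnorm_stats(model: SegmentationModel, images: np.ndarray,
                            batch_size: int = 8, max_batches: int = 5,
                            seed: int = 0) -> None:
    """Re-estimate batch-norm running statistics with equal-weighted passes.

    Running statistics updated by a small-momentum EMA lag behind fast-moving
    weights (worst for tiny datasets), which depresses eval-mode quality.
    This recomputes them from a few seeded batches: batch k is folded in with
    momentum 1/k, yielding an equal-weight average of fresh batch statistics.
    """
    from . import nn as _nn

    bns = [m for m in model.modules() if isinstance(m, _nn.BatchNorm2d)]
    if not bns:
        return
    dps = [m for m in model.modules() if isinstance(m, _nn.DropPath)]
    saved_rates = [dp.rate for dp in dps]
    saved_momenta = [bn.momentum for bn in bns]
    was_training = model.training
    try:
        for dp in dps:
            dp.rate = 0.0
        model.train()
        idx = np.random.default_rng(seed).permutation(images.shape[0])
        take = idx[: batch_size * max_batches]
        for k, start in enumerate(range(0, len(take), batch_size), start=1):
            chunk = images[take[start:start + batch_size]].astype(np.float32)
            padded = np.stack([pad_to_stride(im)[0] for im in chunk])
            for bn in bns:
                bn.momentum = 1.0 / k
            model.forward(Tensor(padded))
    finally:
        for dp, r in zip(dps, saved_rates):
            dp.rate = r
        for bn, m in zip(bns, saved_momenta):
            bn.momentum = m
        model.train(was_training)


def segment_batch(images: np.ndarray, model: SegmentationModel,
                  batch_size: int = 8) -> np.ndarray:
    """Segment a stack of same-sized images (n, 3, H, W) -> (n, H, W) masks."""
    was_training = model.training
    model.eval()
    try:
        masks = []
        for start in range(0, images.shape[0], batch_size):
            chunk = images[start:start + batch_size].astype(np.float32)
            padded = np.stack([pad_to_stride(im)[0] for im in chunk])
            out = model.forward(Tensor(padded))
            H, W = images.shape[2], images.shape[3]
            masks.append(np.argmax(out.data[:, :, :H, :W], axis=1).astype(np.uint8))
    finally:
        model.train(was_training)
    return np.concatenate(masks, axis=0)


def segment(image: np.ndarray, model: SegmentationModel) -> np.ndarray:
    """Binary mask (H, W) with values in {0, 1}: argmax over class logits."""
    was_training = model.training
    model.eval()
    try:
        logits = model.logits_for_image(image)
    finally:
        model.train(was_training)
    return np.argmax(logits.data, axis=0).astype(np.uint8)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _config_payload(model: SegmentationModel) -> str:
    return json.dumps({
        "encoder": asdict(model.encoder_cfg),
        "decoder": asdict(model.decoder_cfg),
        "seed": model.seed,
    })


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, __config__=np.frombuffer(_config_payload(model).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> SegmentationModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        state = {k.replace("/", "."): data[k] for k in data.files if k != "__config__"}
    enc_cfg = EncoderConfig(**{**cfg["encoder"],
                               "channels": tuple(cfg["encoder"]["channels"]),
                               "depths": tuple(cfg["encoder"]["depths"]),
                               "expansion_ratios": tuple(cfg["encoder"]["expansion_ratios"]),
                               "strip_sizes": tuple(cfg["encoder"]["strip_sizes"])})
    dec_cfg = DecoderConfig(**{**cfg["decoder"],
                               "skip_channels": tuple(cfg["decoder"]["skip_channels"])})
    model = SegmentationModel(enc_cfg, dec_cfg, seed=cfg["seed"])
    model.load_state_dict(state)
    return model
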