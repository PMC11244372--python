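"""Seeded generator of tongue-like image/mask pairs plus dataset I/O.

Real clinical photographs of this kind are private, so every other module is
exercised against synthetic scenes that reproduce the documented hard cases:
scalloped (tooth-marked) edges, an inward tip notch, sheared/rotated
("twisted") shapes, whitish coating tints, dark pigment spots, lip-colored
distractor bands, background clutter and illumination jitter.  Generation is
a pure function of the scene spec; masks are the exact rasterized region.

On-disk layout: ``images/*.png``, ``masks/*.png`` ({0, 255} single channel)
and ``manifest.csv`` with columns (id, image_path, mask_path, shape_family,
seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SHAPE_FAMILIES", "SceneSpec", "SegmentationBatch",
    "generate_scene", "sample_spec", "make_dataset", "split_dataset",
    "read_image", "read_mask", "write_mask", "load_batch",
]

SHAPE_FAMILIES = ("smooth", "tooth_marked", "w_tip", "twisted")


@dataclass(frozen=True)
class SceneSpec:
    seed: int
    size: tuple = (64, 64)
    tongue_shape: str = "smooth"
    coating: float = 0.3          # 0 = plain red-pink, 1 = heavy whitish coating
    n_spots: int = 0              # dark pigment spots on the tongue
    distractors: bool = True      # lip bands / face-tone clutter
    brightness: float = 1.0       # illumination jitter in [0.6, 1.4]
    temperature: float = 1.0      # warm/cool tilt in [0.8, 1.25]
    scale_fraction: float = 0.2   # tongue area as a fraction of the frame

    def __post_init__(self):
        if self.tongue_shape not in SHAPE_FAMILIES:
            raise ValueError(f"unknown tongue shape {self.tongue_shape!r}")
        if not 0.02 < self.scale_fraction < 0.6:
            raise ValueError(
                f"scale_fraction must lie in (0.02, 0.6), got {self.scale_fraction}"
            )
        if not 0.0 <= self.coating <= 1.0:
            raise ValueError("coating must lie in [0, 1]")
        if not 0.5 <= self.brightness <= 1.5 or not 0.7 <= self.temperature <= 1.4:
            raise ValueError("illumination jitter out of bounds")
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")


@dataclass
class SegmentationBatch:
    images: np.ndarray                  # (n, 3, H, W) float in [0, 1]
    masks: np.ndarray                   # (n, H, W) uint8 in {0, 1}
    metadata: list = field(default_factory=list)
    phi: np.ndarray | None = None       # optional signed distance maps

    def __post_init__(self):
        if self.images.shape[0] != self.masks.shape[0]:
            raise ValueError("images and masks must pair up")
        if self.images.shape[2:] != self.masks.shape[1:]:
            raise ValueError("mask shapes must match image shapes")
        if not np.all(np.isin(np.unique(self.masks), (0, 1))):
            raise ValueError("masks must be binary")

    def __len__(self) -> int:
        return self.images.shape[0]


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _wrap_angle(t: np.ndarray) -> np.ndarray:
    return (t + np.pi) % (2.0 * np.pi) - np.pi


def _tongue_mask(spec: SceneSpec, rng: np.random.Generator):
    H, W = spec.size
    p = rng.uniform(1.8, 2.6)
    aspect = rng.uniform(0.8, 1.25)
    angle = rng.normal(0.0, 0.12)
    shear = 0.0
    if spec.tongue_shape == "twisted":
        angle = rng.choice((-1.0, 1.0)) * rng.uniform(0.35, 0.6)
        shear = rng.choice((-1.0, 1.0)) * rng.uniform(0.35, 0.6)
    cy = H * rng.uniform(0.42, 0.58)
    cx = W * rng.uniform(0.4, 0.6)
    amp = rng.uniform(0.07, 0.12)
    k_scallop = int(rng.integers(8, 13))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    notch_depth = rng.uniform(0.25, 0.4)
    notch_width = rng.uniform(0.2, 0.3)

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    ca, sa = np.cos(angle), np.sin(angle)
    u0 = ca * (xx - cx) + sa * (yy - cy)
    v0 = -sa * (xx - cx) + ca * (yy - cy)
    u0 = u0 + shear * v0

    target = spec.scale_fraction * H * W
    r = np.sqrt(target / np.pi)

    def render(radius: float) -> np.ndarray:
        a = radius * aspect
        b = radius / aspect
        un, vn = u0 / a, v0 / b
        rho = (np.abs(un) ** p + np.abs(vn) ** p) ** (1.0 / p)
        bound = np.ones_like(rho)
        theta = np.arctan2(vn, un)
        if spec.tongue_shape == "tooth_marked":
            bound = bound + amp * np.sin(k_scallop * theta + phase)
        elif spec.tongue_shape == "w_tip":
            # inward notch at the tip (the +v direction, pointing down-frame)
            d = _wrap_angle(theta - np.pi / 2.0)
            bound = bound - notch_depth * np.exp(-((d / notch_width) ** 2))
        return rho <= bound

    mask = render(r)
    for _ in range(2):
        area = mask.sum()
        if area == 0:
            raise ValueError(f"degenerate scene: tongue rendered with zero area ({spec})")
        r = r * np.sqrt(target / area)
        mask = render(r)
    if mask.sum() == 0:
        raise ValueError(f"degenerate scene: tongue rendered with zero area ({spec})")
    return mask, (cy, cx, r)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene: returns (image (3, H, W) in [0, 1], mask (H, W) in {0, 1})."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    mask, (cy, cx, r) = _tongue_mask(spec, rng)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    # face-tone background with a soft vertical gradient
    base = np.array([0.82, 0.62, 0.52]) * rng.uniform(0.9, 1.1)
    img = np.empty((H, W, 3))
    grad = 1.0 - 0.25 * (yy / max(H - 1, 1))
    for ch in range(3):
        img[..., ch] = base[ch] * grad

    if spec.distractors:
        # muted clutter patches
        for _ in range(int(rng.integers(2, 5))):
            ph, pw = rng.integers(H // 8, H // 2), rng.integers(W // 8, W // 2)
            py, px = rng.integers(0, H - ph + 1), rng.integers(0, W - pw + 1)
            col = rng.uniform(0.2, 0.8, size=3)
            img[py:py + ph, px:px + pw] = 0.6 * img[py:py + ph, px:px + pw] + 0.4 * col
        # lip-colored band: an annulus sector hugging the tongue
        lip = np.array([0.72, 0.33, 0.37]) * rng.uniform(0.9, 1.1)
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        width = r * rng.uniform(0.2, 0.35)
        band = (dist > r * 1.02) & (dist < r * 1.02 + width)
        theta = np.arctan2(yy - cy, xx - cx)
        sector = np.abs(_wrap_angle(theta + np.pi / 2.0)) < rng.uniform(0.9, 1.5)
        band &= sector
        img[band] = 0.25 * img[band] + 0.75 * lip

    # tongue coloring: pink-red body, whitish coating toward the center
    body = np.array([0.78, 0.38, 0.42]) + rng.normal(0.0, 0.02, size=3)
    coat_col = np.array([0.88, 0.85, 0.80])
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    center_w = np.exp(-((dist / max(r, 1e-6)) ** 2))
    coat_w = np.clip(spec.coating * center_w, 0.0, 1.0)
    tongue_rgb = body[None, None, :] * (1.0 - coat_w[..., None]) + coat_col * coat_w[..., None]
    img[mask] = tongue_rgb[mask]

    # dark pigment spots inside the tongue
    fg_idx = np.argwhere(mask)
    for _ in range(spec.n_spots):
        sy, sx = fg_idx[rng.integers(len(fg_idx))]
        sr = rng.uniform(1.0, max(2.0, r * 0.15))
        spot = ((yy - sy) ** 2 + (xx - sx) ** 2 <= sr ** 2) & mask
        img[spot] = np.array([0.30, 0.16, 0.20])

    # illumination jitter: brightness + color temperature, then sensor noise
    img *= spec.brightness
    img[..., 0] *= spec.temperature
    img[..., 2] /= spec.temperature
    img = ndimage.gaussian_filter(img, sigma=(0.6, 0.6, 0.0))
    img += rng.normal(0.0, 0.015, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return img.transpose(2, 0, 1), mask.astype(np.uint8)


def sample_spec(seed: int, size: tuple = (64, 64),
                tongue_shape: str | None = None) -> SceneSpec:
    """Draw a varied scene spec deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    shape = tongue_shape or SHAPE_FAMILIES[rng.integers(len(SHAPE_FAMILIES))]
    return SceneSpec(
        seed=seed,
        size=tuple(size),
        tongue_shape=shape,
        coating=float(rng.uniform(0.0, 0.8)),
        n_spots=int(rng.integers(0, 4)),
        distractors=True,
        brightness=float(rng.uniform(0.75, 1.3)),
        temperature=float(rng.uniform(0.85, 1.2)),
        scale_fraction=float(rng.uniform(0.10, 0.45)),
    )


# ---------------------------------------------------------------------------
# dataset assembly and I/O
# ---------------------------------------------------------------------------

def make_dataset(n: int, size: tuple = (64, 64), seed: int = 0,
                 out_dir: str | Path | None = None) -> SegmentationBatch:
    """Generate ``n`` scenes; optionally write images/masks/manifest to disk."""
    if n < 1:
        raise ValueError(f"dataset size must be >= 1, got {n}")
    master = np.random.default_rng(seed)
    images, masks, meta = [], [], []
    for i in range(n):
        item_seed = int(master.integers(2 ** 31 - 1))
        family = SHAPE_FAMILIES[int(master.integers(len(SHAPE_FAMILIES)))]
        spec = sample_spec(item_seed, size=size, tongue_shape=family)
        img, mask = generate_scene(spec)
        images.append(img)
        masks.append(mask)
        meta.append(spec)
    batch = SegmentationBatch(images=np.stack(images).astype(np.float32),
                              masks=np.stack(masks), metadata=meta)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        rows = []
        for i, spec in enumerate(meta):
            img_path = out / "images" / f"{i:05d}.png"
            mask_path = out / "masks" / f"{i:05d}.png"
            arr = (batch.images[i].transpose(1, 2, 0) * 255).round().astype(np.uint8)
            Image.fromarray(arr).save(img_path)
            write_mask(mask_path, batch.masks[i])
            rows.append({"id": i, "image_path": str(img_path.relative_to(out)),
                         "mask_path": str(mask_path.relative_to(out)),
                         "shape_family": spec.tongue_shape, "seed": spec.seed})
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return batch


def split_dataset(manifest, ratio: float = 0.8, seed: int = 0):
    """Seeded shuffle-and-split into disjoint, exhaustive (train, test) id lists.

    ``manifest`` is a manifest.csv path, a row list, or an integer count.
    The split point is round-half-up of n * ratio.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    if isinstance(manifest, (str, Path)):
        ids = [int(row["id"]) for row in _read_manifest(manifest)]
    elif isinstance(manifest, int):
        ids = list(range(manifest))
    else:
        ids = [int(row["id"]) for row in manifest]
    n = len(ids)
    if n < 2:
        raise ValueError(f"need at least 2 items to split, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    k = int(np.floor(n * ratio + 0.5))
    shuffled = [ids[i] for i in order]
    return shuffled[:k], shuffled[k:]


def _read_manifest(path: str | Path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def read_image(path: str | Path) -> np.ndarray:
    """Decode PNG/JPEG to an RGB (3, H, W) float array in [0, 1]."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return arr.transpose(2, 0, 1)


def read_mask(path: str | Path) -> np.ndarray:
    """Decode a single-channel mask PNG; any nonzero pixel becomes foreground."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write an in-memory {0, 1} mask as a {0, 255} single-channel PNG."""
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary {0, 1}")
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def load_batch(dataset_dir: str | Path, ids=None) -> SegmentationBatch:
    """Reload a dataset written by :func:`make_dataset`, optionally a subset."""
    root = Path(dataset_dir)
    rows = _read_manifest(root / "manifest.csv")
    if ids is not None:
        wanted = set(int(i) for i in ids)
        rows = [r for r in rows if int(r["id"]) in wanted]
    if not rows:
        raise ValueError(f"no dataset rows selected from {root}")
    images = np.stack([read_image(root / r["image_path"]) for r in rows])
    masks = np.stack([read_mask(root / r["mask_path"]) for r in rows])
    return SegmentationBatch(images=images, masks=masks, metadata=rows)
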