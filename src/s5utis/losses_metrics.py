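"""Training losses and evaluation metrics for binary segmentation.

Metrics (Dice, mIoU, pixel accuracy) are exact integer arithmetic over
pixel confusion counts.  The boundary loss integrates the predicted
foreground probability against the signed distance to the ground-truth
contour (negative inside), discretized as a mean so its scale is
resolution-independent.

Empty-region convention: a ratio with zero denominator counts as 1 when the
class is absent from both masks and 0 when absent from exactly one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import functional as F
from .nn.tensor import Tensor, as_tensor, mean as t_mean, mul as t_mul

__all__ = [
    "ConfusionCounts", "DistanceMap",
    "confusion", "dice", "miou", "pixel_accuracy",
    "signed_distance", "boundary_loss", "cross_entropy", "combined_loss",
    "evaluate_pairs",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


@dataclass(frozen=True)
class DistanceMap:
    """Signed per-pixel distance to the ground-truth boundary (negative inside)."""

    phi: np.ndarray


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1); found values {uniq[:5]}")
    return arr.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact TP/TN/FP/FN pixel tallies; shapes must match."""
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def _safe_ratio(num: int, den: int) -> float:
    if den == 0:
        return 1.0
    return num / den


def dice(c: ConfusionCounts) -> float:
    """2 TP / (FP + 2 TP + FN); 1.0 when both regions are empty."""
    return _safe_ratio(2 * c.TP, c.FP + 2 * c.TP + c.FN)


def miou(c: ConfusionCounts) -> float:
    """Mean of foreground IoU TP/(TP+FP+FN) and background IoU TN/(TN+FN+FP)."""
    fg = _safe_ratio(c.TP, c.TP + c.FP + c.FN)
    bg = _safe_ratio(c.TN, c.TN + c.FN + c.FP)
    return 0.5 * (fg + bg)


def pixel_accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    return _safe_ratio(c.TP + c.TN, c.total)


# ---------------------------------------------------------------------------
# boundary loss
# ---------------------------------------------------------------------------

def signed_distance(truth: np.ndarray) -> DistanceMap:
    """Signed Euclidean distance to the nearest boundary pixel of the mask.

    Boundary pixels are foreground pixels 4-adjacent to background; they get
    phi = 0, interior pixels negative distances, exterior positive.  A mask
    without both classes has no boundary: returns all-zero phi with a warning.
    """
    g = _check_binary(truth, "truth")
    n_fg = int(g.sum())
    if n_fg == 0 or n_fg == g.size:
        warnings.warn("degenerate mask (single class): signed distance is all zeros",
                      stacklevel=2)
        return DistanceMap(phi=np.zeros(g.shape, dtype=float))
    four = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(g, structure=four)
    boundary = g & ~interior
    dist = ndimage.distance_transform_edt(~boundary)
    phi = np.where(g, -dist, dist)
    return DistanceMap(phi=phi)


def boundary_loss(probs, phi: DistanceMap):
    """Mean over pixels of phi * foreground probability.

    Accepts a plain array (returns a float) or a graph tensor (returns a
    scalar tensor so gradients flow into the probabilities).
    """
    phi_arr = phi.phi if isinstance(phi, DistanceMap) else np.asarray(phi)
    if isinstance(probs, Tensor):
        if probs.shape != phi_arr.shape:
            raise ValueError(f"shape mismatch: probs {probs.shape} vs phi {phi_arr.shape}")
        return t_mean(t_mul(probs, Tensor(phi_arr.astype(probs.dtype))))
    probs = np.asarray(probs, dtype=float)
    if probs.shape != phi_arr.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs phi {phi_arr.shape}")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float((phi_arr * probs).mean())


def cross_entropy(logits, truth: np.ndarray):
    """Mean per-pixel cross-entropy; logits (B, K, H, W), truth integer (B, H, W)."""
    return F.softmax_cross_entropy(as_tensor(logits), np.asarray(truth, dtype=np.int64))


def combined_loss(logits, truth: np.ndarray, alpha: float = 1.0,
                  phi: np.ndarray | DistanceMap | None = None):
    """alpha * CE + (1 - alpha) * boundary loss of the softmaxed foreground.

    ``alpha=1`` short-circuits to plain cross-entropy (bitwise identical).
    ``phi`` may be precomputed; otherwise derived from ``truth`` per image.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    logits = as_tensor(logits)
    truth = np.asarray(truth)
    ce = cross_entropy(logits, truth)
    if alpha == 1.0:
        return ce
    if phi is None:
        phi_arr = np.stack([signed_distance(truth[b]).phi for b in range(truth.shape[0])])
    else:
        phi_arr = phi.phi if isinstance(phi, DistanceMap) else np.asarray(phi)
        if phi_arr.shape != truth.shape:
            phi_arr = np.broadcast_to(phi_arr, truth.shape)
    fg = F.softmax(logits, axis=1)
    # slice out the foreground class plane
    from .nn.tensor import make_op
    p = fg.data[:, 1]

    def backward(g):
        gx = np.zeros_like(fg.data)
        gx[:, 1] = g
        return (gx,)

    p_t = make_op(p, (fg,), backward)
    bl = boundary_loss(p_t, DistanceMap(phi=phi_arr))
    if alpha == 0.0:
        return bl
    return t_mul(ce, alpha) + t_mul(bl, 1.0 - alpha)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def evaluate_pairs(pairs, average: str = "micro") -> dict:
    """Aggregate Dice/mIoU/PA over (pred, truth) mask pairs.

    ``micro`` pools confusion counts over the whole set (default); ``macro``
    averages per-image scores.  Returns aggregate values plus per-image rows.
    """
    if average not in ("micro", "macro"):
        raise ValueError(f"unknown averaging mode {average!r}")
    per_image = []
    total = ConfusionCounts(0, 0, 0, 0)
    for i, (pred, truth) in enumerate(pairs):
        c = confusion(pred, truth)
        total = total + c
        per_image.append({"index": i, "dice": dice(c), "miou": miou(c),
                          "pixel_accuracy": pixel_accuracy(c)})
    if not per_image:
        raise ValueError("cannot evaluate an empty dataset")
    if average == "micro":
        agg = {"dice": dice(total), "miou": miou(total),
               "pixel_accuracy": pixel_accuracy(total)}
    else:
        agg = {k: float(np.mean([r[k] for r in per_image]))
               for k in ("dice", "miou", "pixel_accuracy")}
    return {"aggregate": agg, "per_image": per_image, "average": average,
            "n_images": len(per_image)}
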