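"""Segmentation evaluation metrics: Dice, IoU, pixel accuracy, Hausdorff.

All four operate on binary masks (values in {0, 1}). The symmetric
Hausdorff distance is defined only when both masks contain positive pixels;
otherwise it is *undefined* (``None``) and must be excluded from averages
rather than treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MetricBundle",
    "dice",
    "iou",
    "pixel_accuracy",
    "hausdorff_symmetric",
    "metric_bundle",
]


@dataclass(frozen=True)
class MetricBundle:
    dice: float
    iou: float
    pixel_accuracy: float
    hausdorff: float | None  # None means undefined (an empty mask)


def _as_binary(name: str, m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.dtype == bool:
        return m
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} is not binary; values found: {vals[:8]}")
    return m.astype(bool)


def _pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = _as_binary("pred", pred)
    g = _as_binary("gt", gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return p, g


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1.0 when both masks are empty."""
    p, g = _pair(pred, gt)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """|A∩B| / |A∪B|; defined as 1.0 when both masks are empty."""
    p, g = _pair(pred, gt)
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def pixel_accuracy(pred: np.ndarray, gt: np.ndarray) -> float:
    p, g = _pair(pred, gt)
    return float((p == g).mean())


def hausdorff_symmetric(pred: np.ndarray, gt: np.ndarray) -> float | None:
    """Symmetric Hausdorff distance between positive-pixel sets, in pixels.

    Euclidean distances between pixel centers; ``None`` (undefined) when
    either mask is empty.
    """
    p, g = _pair(pred, gt)
    pa = np.argwhere(p)
    ga = np.argwhere(g)
    if len(pa) == 0 or len(ga) == 0:
        return None
    tree_p = cKDTree(pa)
    tree_g = cKDTree(ga)
    d_pg = tree_g.query(pa, k=1)[0].max()
    d_gp = tree_p.query(ga, k=1)[0].max()
    return float(max(d_pg, d_gp))


def metric_bundle(pred: np.ndarray, gt: np.ndarray) -> MetricBundle:
    """All four metrics for one mask pair."""
    return MetricBundle(
        dice=dice(pred, gt),
        iou=iou(pred, gt),
        pixel_accuracy=pixel_accuracy(pred, gt),
        hausdorff=hausdorff_symmetric(pred, gt),
    )
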