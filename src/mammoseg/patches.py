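"""Lesion-centered patch extraction and the hybrid batch generator.

Stage-1 pretraining consumes 224×224 crops: positive patches centered on
the lesion centroid (with random jitter), and background patches sampled at
a 2:1 negative-to-positive ratio subject to a <5% mask-coverage limit so
lesion tissue is not inadvertently labeled background. The patch dataset is
split 80/20 *by source image* to avoid leakage between splits.

Stage-2 fine-tuning consumes a hybrid stream in which each sample is,
independently with probability 0.35, a positive lesion patch instead of a
full (resized) image — keeping small-lesion features present in training
batches so they are not forgotten during full-image fine-tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from mammoseg.phantom import ImagePair

__all__ = [
    "PatchSample",
    "SamplerConfig",
    "LesionBBox",
    "lesion_bbox",
    "extract_positive_patch",
    "sample_negative_patches",
    "build_patch_dataset",
    "hybrid_batches",
    "save_patch_dataset",
    "load_patch_dataset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LesionBBox:
    rmin: int
    rmax: int
    cmin: int
    cmax: int
    centroid: tuple[float, float]


@dataclass
class PatchSample:
    image_crop: np.ndarray
    mask_crop: np.ndarray
    label: str               # 'positive' | 'negative'
    source_id: str
    origin: tuple[int, int]  # top-left corner in the source image

    def __post_init__(self):
        if self.label not in ("positive", "negative"):
            raise ValueError("label must be 'positive' or 'negative'")
        cov = float(self.mask_crop.mean())
        if self.label == "positive" and self.mask_crop.sum() == 0:
            raise ValueError("positive patch with empty mask")
        if self.label == "negative" and cov >= 0.05:
            raise ValueError(f"negative patch with mask coverage {cov:.3f} >= 5%")

    @property
    def coverage(self) -> float:
        return float(self.mask_crop.mean())


@dataclass(frozen=True)
class SamplerConfig:
    patch_side: int = 224
    neg_per_pos: int = 2
    neg_max_coverage: float = 0.05
    centroid_jitter_frac: float = 0.25
    split_train_frac: float = 0.8
    hybrid_substitution_prob: float = 0.35
    positives_per_lesion: int = 1
    restrict_to_foreground: bool = True
    foreground_threshold: float = 0.1
    foreground_min_frac: float = 0.5
    attempt_budget: int = 100
    seed: int = 0


def lesion_bbox(mask: np.ndarray) -> LesionBBox | None:
    """Tight bounding box + centroid of positive pixels; None if empty."""
    pos = np.argwhere(np.asarray(mask) > 0)
    if len(pos) == 0:
        return None
    (rmin, cmin), (rmax, cmax) = pos.min(axis=0), pos.max(axis=0)
    cy, cx = pos.mean(axis=0)
    return LesionBBox(int(rmin), int(rmax), int(cmin), int(cmax), (float(cy), float(cx)))


def _clamp_topleft(center_r: float, center_c: float, side: int,
                   h: int, w: int) -> tuple[int, int]:
    r = int(round(center_r - side / 2))
    c = int(round(center_c - side / 2))
    return int(np.clip(r, 0, h - side)), int(np.clip(c, 0, w - side))


def extract_positive_patch(pair: ImagePair, config: SamplerConfig,
                           rng: np.random.Generator) -> PatchSample:
    """A lesion-centered crop with uniform centroid jitter, clamped in-bounds."""
    h, w = pair.image.shape
    s = config.patch_side
    for dim, size in (("height", h), ("width", w)):
        if size < s:
            raise ValueError(f"source image {dim} {size} < patch side {s}")
    bbox = lesion_bbox(pair.mask)
    if bbox is None:
        raise ValueError(f"cannot extract a positive patch from empty mask ({pair.id})")
    jit = config.centroid_jitter_frac * s
    cy = bbox.centroid[0] + rng.uniform(-jit, jit)
    cx = bbox.centroid[1] + rng.uniform(-jit, jit)
    r0, c0 = _clamp_topleft(cy, cx, s, h, w)
    crop_m = pair.mask[r0:r0 + s, c0:c0 + s]
    if crop_m.sum() == 0:
        # extreme jitter can push a tiny lesion out; recenter exactly
        r0, c0 = _clamp_topleft(*bbox.centroid, s, h, w)
        crop_m = pair.mask[r0:r0 + s, c0:c0 + s]
    return PatchSample(
        image_crop=pair.image[r0:r0 + s, c0:c0 + s].copy(),
        mask_crop=crop_m.copy(),
        label="positive", source_id=pair.id, origin=(r0, c0))


def _foreground(pair: ImagePair, threshold: float) -> np.ndarray:
    return pair.image > threshold


def sample_negative_patches(pair: ImagePair, config: SamplerConfig,
                            rng: np.random.Generator,
                            n: int | None = None) -> list[PatchSample]:
    """Rejection-sample background patches with mask coverage < the limit.

    Candidate windows must overlap the breast foreground (≥50% foreground
    pixels) when that filter is enabled. Returns fewer than requested (with
    a warning) if the attempt budget runs out; never mislabels.
    """
    h, w = pair.image.shape
    s = config.patch_side
    for dim, size in (("height", h), ("width", w)):
        if size < s:
            raise ValueError(f"source image {dim} {size} < patch side {s}")
    n = config.neg_per_pos if n is None else n
    fg = _foreground(pair, config.foreground_threshold) if config.restrict_to_foreground else None
    out: list[PatchSample] = []
    for _ in range(n):
        found = False
        for _attempt in range(config.attempt_budget):
            r0 = int(rng.integers(0, h - s + 1))
            c0 = int(rng.integers(0, w - s + 1))
            crop_m = pair.mask[r0:r0 + s, c0:c0 + s]
            if crop_m.mean() >= config.neg_max_coverage:
                continue
            if fg is not None and fg[r0:r0 + s, c0:c0 + s].mean() < config.foreground_min_frac:
                continue
            out.append(PatchSample(
                image_crop=pair.image[r0:r0 + s, c0:c0 + s].copy(),
                mask_crop=crop_m.copy(),
                label="negative", source_id=pair.id, origin=(r0, c0)))
            found = True
            break
        if not found:
            log.warning("negative-patch budget exhausted for %s: %d/%d sampled",
                        pair.id, len(out), n)
            break
    return out


def build_patch_dataset(pairs: Sequence[ImagePair], config: SamplerConfig
                        ) -> tuple[list[PatchSample], list[PatchSample]]:
    """Positive + ratio-controlled negative patches, split 80/20 by image.

    All patches from one source image land in the same split, so validation
    patches never share an image with training patches.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 source images to split")
    rng = np.random.default_rng(config.seed)
    ids = [p.id for p in pairs]
    order = rng.permutation(len(ids))
    n_train = int(round(config.split_train_frac * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train_ids = {ids[i] for i in order[:n_train]}
    train: list[PatchSample] = []
    val: list[PatchSample] = []
    for pair in pairs:
        if pair.lesion_area == 0:
            log.warning("skipping %s: empty mask, no lesion to center on", pair.id)
            continue
        dest = train if pair.id in train_ids else val
        for _ in range(config.positives_per_lesion):
            pos = extract_positive_patch(pair, config, rng)
            dest.append(pos)
            dest.extend(sample_negative_patches(pair, config, rng))
    return train, val


def save_patch_dataset(patches: Sequence[PatchSample], outdir) -> None:
    """Persist patches as PNGs plus a CSV index.

    Layout: ``images/<patch_id>.png``, ``masks/<patch_id>.png`` and
    ``index.csv`` with columns patch_id, source_id, label, origin_row,
    origin_col, coverage.
    """
    import imageio.v3 as iio
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        pid = f"patch-{i:05d}"
        iio.imwrite(outdir / "images" / f"{pid}.png",
                    np.round(p.image_crop * 65535).astype(np.uint16))
        iio.imwrite(outdir / "masks" / f"{pid}.png",
                    (p.mask_crop.astype(np.uint32) * 65535).astype(np.uint16))
        rows.append({"patch_id": pid, "source_id": p.source_id, "label": p.label,
                     "origin_row": p.origin[0], "origin_col": p.origin[1],
                     "coverage": p.coverage})
    pd.DataFrame(rows).to_csv(outdir / "index.csv", index=False)


def load_patch_dataset(outdir) -> list[PatchSample]:
    """Read a patch dataset written by :func:`save_patch_dataset`."""
    import imageio.v3 as iio
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    index = pd.read_csv(outdir / "index.csv")
    out = []
    for _, row in index.iterrows():
        img = iio.imread(outdir / "images" / f"{row.patch_id}.png")
        msk = iio.imread(outdir / "masks" / f"{row.patch_id}.png")
        out.append(PatchSample(
            image_crop=(img.astype(np.float32) / 65535),
            mask_crop=(msk > 32767).astype(np.uint8),
            label=str(row.label), source_id=str(row.source_id),
            origin=(int(row.origin_row), int(row.origin_col))))
    return out


def hybrid_batches(full_pairs: Sequence[ImagePair],
                   patch_pool: Sequence[PatchSample],
                   config: SamplerConfig,
                   rng: np.random.Generator,
                   batch_size: int = 8,
                   n_batches: int | None = None,
                   ) -> Iterator[tuple[np.ndarray, np.ndarray, list[str]]]:
    """Yield ``(images, masks, provenance)`` training batches.

    Each sample is, independently with probability
    ``hybrid_substitution_prob``, a positive lesion patch from the pool;
    otherwise a full image. Provenance entries are ``'patch'`` or
    ``'full'``. Runs one epoch (one pass worth of ``len(full_pairs)``
    samples) when ``n_batches`` is None.
    """
    if not full_pairs:
        raise ValueError("full_pairs is empty")
    p_sub = config.hybrid_substitution_prob
    positives = [p for p in patch_pool if p.label == "positive"]
    if p_sub > 0 and not positives:
        raise ValueError("hybrid substitution requires a non-empty positive patch pool")
    side = full_pairs[0].image.shape[0]
    for p in positives:
        if p.image_crop.shape[0] != side:
            raise ValueError("patch size does not match full-image input size")
    if n_batches is None:
        n_batches = int(np.ceil(len(full_pairs) / batch_size))
    order = rng.permutation(len(full_pairs))
    k = 0
    for _ in range(n_batches):
        imgs, msks, prov = [], [], []
        for _ in range(batch_size):
            if p_sub > 0 and rng.random() < p_sub:
                s = positives[int(rng.integers(len(positives)))]
                imgs.append(s.image_crop)
                msks.append(s.mask_crop)
                prov.append("patch")
            else:
                pair = full_pairs[order[k % len(order)]]
                k += 1
                imgs.append(pair.image)
                msks.append(pair.mask)
                prov.append("full")
        x = np.stack(imgs)[:, None].astype(np.float32)
        y = np.stack(msks)[:, None].astype(np.float32)
        yield x, y, prov
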