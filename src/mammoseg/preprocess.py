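"""Normalization, CLAHE, resizing, mask binarization, and augmentation.

The deterministic pipeline is: min–max normalize to [0, 1], then Contrast
Limited Adaptive Histogram Equalization (clip limit 2.0 in multiples of the
uniform histogram height, 8×8 tile grid), then downsample to the model's
224×224 input; masks are binarized at 0.5 (strict ``>``) and re-binarized
after any interpolation so the alphabet stays {0, 1}.

Stochastic augmentation (rotation, horizontal flip, elastic deformation,
zoom, lesion-preserving cropping, and randomized CLAHE re-application)
applies identical geometric transforms to image and mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage import exposure, transform

from mammoseg.phantom import ImagePair

__all__ = [
    "PreprocessConfig",
    "AugmentConfig",
    "normalize_and_enhance",
    "binarize_mask",
    "resize_pair",
    "preprocess_pair",
    "augment",
    "dataset_stats",
]

log = logging.getLogger(__name__)

_CLAHE_NBINS = 256


@dataclass(frozen=True)
class PreprocessConfig:
    clahe_clip_limit: float = 2.0    # multiples of the uniform bin height
    clahe_tile_grid: int = 8         # 8 means an 8x8 tile grid
    target_side: int = 224
    mask_threshold: float = 0.5
    # 'bilinear' interpolation for the big downsample; 'area' averaging is
    # available as an alternative that aliases less on fine texture
    resize_method: str = "bilinear"

    def __post_init__(self):
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be > 0")
        if self.clahe_tile_grid < 1:
            raise ValueError("clahe_tile_grid must be >= 1")
        if not 0.0 < self.mask_threshold < 1.0:
            raise ValueError("mask_threshold must be in (0, 1)")
        if self.resize_method not in ("bilinear", "area"):
            raise ValueError("resize_method must be 'bilinear' or 'area'")


@dataclass(frozen=True)
class AugmentConfig:
    """Per-transform application probability applies to each transform
    independently; rotation magnitude is drawn from [0, rotation_deg_max]
    with a random sign, zoom magnitude from [0, zoom_max_frac]."""

    rotation_deg_max: float = 10.0
    hflip: bool = True
    elastic: bool = True
    elastic_alpha: float = 30.0   # displacement amplitude, px at 224 scale
    elastic_sigma: float = 6.0    # displacement smoothness, px
    zoom_max_frac: float = 0.12
    lesion_preserving_crop: bool = True
    crop_frac: float = 0.9        # crop window side as a fraction of the image
    clahe_jitter: bool = True     # randomized CLAHE re-application
    p_apply: float = 0.5


def normalize_and_enhance(image: np.ndarray,
                          config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Min–max normalize to [0, 1] and apply CLAHE.

    A constant image has no contrast to equalize and maps to all zeros
    (with a warning) rather than dividing by a zero range.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    lo, hi = float(image.min()), float(image.max())
    if hi - lo <= 0:
        log.warning("constant image: returning all zeros")
        return np.zeros_like(image, dtype=np.float32)
    norm = (image - lo) / (hi - lo)
    kernel = tuple(max(s // config.clahe_tile_grid, 1) for s in norm.shape)
    out = exposure.equalize_adapthist(
        norm, kernel_size=kernel,
        clip_limit=config.clahe_clip_limit / _CLAHE_NBINS, nbins=_CLAHE_NBINS)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def binarize_mask(mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 where value is strictly greater than the threshold, else 0."""
    mask = np.asarray(mask)
    if not np.isfinite(mask).all():
        raise ValueError("mask contains non-finite values")
    return (mask > threshold).astype(np.uint8)


def _resize_image(image: np.ndarray, side: int, method: str) -> np.ndarray:
    if method == "area":
        return transform.resize_local_mean(image, (side, side)).astype(np.float32)
    return transform.resize(image, (side, side), order=1, anti_aliasing=True,
                            preserve_range=True).astype(np.float32)


def resize_pair(pair: ImagePair, target_side: int,
                config: PreprocessConfig = PreprocessConfig()) -> ImagePair:
    """Resample an image/mask pair to ``target_side``.

    The mask is interpolated bilinearly and re-binarized at 0.5; the native
    lesion area is preserved on the returned pair so both resolutions'
    areas stay available downstream.
    """
    if target_side < 32:
        raise ValueError("target_side must be >= 32")
    if target_side > pair.native_side:
        log.info("upsampling %s from %d to %d", pair.id, pair.native_side, target_side)
    img = _resize_image(pair.image, target_side, config.resize_method)
    msk_f = transform.resize(pair.mask.astype(np.float64), (target_side, target_side),
                             order=1, anti_aliasing=False)
    msk = binarize_mask(msk_f, 0.5)
    return ImagePair(id=pair.id, image=np.clip(img, 0.0, 1.0), mask=msk,
                     native_side=pair.native_side,
                     lesion_area_native=pair.lesion_area_native)


def preprocess_pair(pair: ImagePair,
                    config: PreprocessConfig = PreprocessConfig(),
                    resize: bool = True) -> ImagePair:
    """Normalize + CLAHE the image, binarize the mask, optionally resize."""
    img = normalize_and_enhance(pair.image, config)
    msk = binarize_mask(pair.mask, config.mask_threshold)
    out = ImagePair(id=pair.id, image=img, mask=msk, native_side=pair.native_side,
                    lesion_area_native=pair.lesion_area_native)
    if resize:
        out = resize_pair(out, config.target_side, config)
    return out


def _warp_pair(image, mask, rotation_deg, scale, center):
    tf = (transform.AffineTransform(translation=-np.array(center))
          + transform.AffineTransform(rotation=np.deg2rad(rotation_deg), scale=scale)
          + transform.AffineTransform(translation=np.array(center)))
    img = transform.warp(image, tf.inverse, order=1, preserve_range=True)
    msk = transform.warp(mask.astype(np.float64), tf.inverse, order=1, preserve_range=True)
    return img, msk


def _elastic(image, mask, alpha, sigma, rng):
    shape = image.shape
    dr = gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    dc = gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = np.array([rr + dr, cc + dc])
    img = map_coordinates(image, coords, order=1, mode="reflect")
    msk = map_coordinates(mask.astype(np.float64), coords, order=1, mode="reflect")
    return img, msk


def _augment_once(pair: ImagePair, config: AugmentConfig,
                  pp: PreprocessConfig, rng: np.random.Generator) -> ImagePair:
    img = pair.image.astype(np.float64)
    msk = pair.mask.astype(np.float64)
    side = img.shape[0]
    if config.hflip and rng.random() < config.p_apply:
        img, msk = img[:, ::-1], msk[:, ::-1]
    rot = 0.0
    scale = 1.0
    if config.rotation_deg_max > 0 and rng.random() < config.p_apply:
        rot = rng.uniform(0, config.rotation_deg_max) * rng.choice([-1.0, 1.0])
    if config.zoom_max_frac > 0 and rng.random() < config.p_apply:
        mag = rng.uniform(0, config.zoom_max_frac)
        scale = 1.0 + mag if rng.random() < 0.5 else 1.0 / (1.0 + mag)
    if rot != 0.0 or scale != 1.0:
        img, msk = _warp_pair(img, msk, rot, scale, ((side - 1) / 2, (side - 1) / 2))
    if config.elastic and rng.random() < config.p_apply:
        # scale deformation parameters with resolution (defaults are for 224)
        f = side / 224.0
        img, msk = _elastic(img, msk, config.elastic_alpha * f,
                            config.elastic_sigma * f, rng)
    if config.lesion_preserving_crop and rng.random() < config.p_apply:
        win = max(int(round(side * config.crop_frac)), 32)
        def _pick(lesion_lo: int, lesion_hi: int) -> int:
            # window start range that keeps [lesion_lo, lesion_hi] inside
            lo = max(lesion_hi - win + 1, 0)
            hi = min(lesion_lo, side - win)
            if lo > hi:  # lesion bbox larger than the window: clamp
                return int(np.clip(lo, 0, side - win))
            return int(rng.integers(lo, hi + 1))

        mb = np.argwhere(msk > 0.5)
        if len(mb):
            (rmin, cmin), (rmax, cmax) = mb.min(axis=0), mb.max(axis=0)
            lo_r, lo_c = _pick(rmin, rmax), _pick(cmin, cmax)
        else:
            lo_r = int(rng.integers(0, side - win + 1))
            lo_c = int(rng.integers(0, side - win + 1))
        img = transform.resize(img[lo_r:lo_r + win, lo_c:lo_c + win], (side, side),
                               order=1, preserve_range=True)
        msk = transform.resize(msk[lo_r:lo_r + win, lo_c:lo_c + win], (side, side),
                               order=1, preserve_range=True)
    if config.clahe_jitter and rng.random() < config.p_apply:
        clip = rng.uniform(1.0, 3.0)
        img = normalize_and_enhance(img, replace(pp, clahe_clip_limit=clip)).astype(np.float64)
    return ImagePair(id=pair.id, image=np.clip(img, 0, 1).astype(np.float32),
                     mask=binarize_mask(msk, 0.5), native_side=pair.native_side,
                     lesion_area_native=pair.lesion_area_native)


def augment(pair: ImagePair, config: AugmentConfig,
            rng: np.random.Generator,
            preprocess_config: PreprocessConfig = PreprocessConfig()) -> ImagePair:
    """Random augmentation with image/mask lockstep.

    When ``lesion_preserving_crop`` is enabled and the input mask is
    non-empty, the output mask is guaranteed non-empty: draws that lose the
    lesion (e.g. an extreme warp) are re-drawn, falling back to the
    untransformed pair after a bounded number of attempts.
    """
    had_lesion = pair.lesion_area > 0
    for _ in range(8):
        out = _augment_once(pair, config, preprocess_config, rng)
        if not (config.lesion_preserving_crop and had_lesion) or out.lesion_area > 0:
            return out
    log.warning("augmentation kept losing the lesion for %s; returning input", pair.id)
    return pair


def dataset_stats(pairs: list[ImagePair]) -> dict:
    """Sparsity summary: totals, positive pixels, lesion-to-background ratio."""
    if not pairs:
        raise ValueError("dataset_stats requires a non-empty list")
    areas = [p.lesion_area for p in pairs]
    total = int(sum(p.mask.size for p in pairs))
    positive = int(sum(areas))
    background = total - positive
    return {
        "n_images": len(pairs),
        "total_pixels": total,
        "positive_pixels": positive,
        "lesion_to_background_ratio": positive / background if background else float("inf"),
        "per_image_areas": areas,
    }
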