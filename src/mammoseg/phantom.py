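"""Synthetic mammographic phantoms with exact lesion ground truth.

The generator renders a breast-shaped half-ellipse foreground with
multiscale correlated texture (smoothed white noise), then inserts 0–N
lesions as smooth irregular blobs: each blob is a star-shaped region whose
radius varies with angle by low-frequency periodic noise, with a soft
Gaussian-profile intensity uplift so boundaries are low contrast. The blob
radius scale is solved analytically from the requested pixel area, so the
rasterized mask area lands within a few percent of the target. Masks record
exactly the rendered lesion pixels.

These phantoms stress the behaviors that matter for the pipeline — tiny
low-contrast targets, irregular boundaries, heavy class imbalance — without
claiming radiographic realism (no X-ray physics, no calcifications, no
CC/MLO geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter

__all__ = [
    "PhantomConfig",
    "ImagePair",
    "InfeasibleConfigurationError",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
    "apportion",
    "DEFAULT_AREA_RANGES",
    "DEFAULT_CONTRAST_BY_CATEGORY",
    "SIZE_CATEGORIES",
]

SIZE_CATEGORIES = ("small", "medium", "large")

# Pixel-area sampling intervals per size category. The category boundaries
# (500 and 1500 px) follow the small/<500, medium/500-1500, large/>1500
# stratification used in the evaluation module.
DEFAULT_AREA_RANGES: dict[str, tuple[float, float]] = {
    "small": (60, 499),
    "medium": (500, 1500),
    "large": (1501, 4500),
}

# Smaller lesions are rendered fainter: in screening practice subtle early
# lesions are both small and low contrast, and this is what makes the
# size-dependent detection gradient emerge in a trained model.
DEFAULT_CONTRAST_BY_CATEGORY: dict[str, float] = {
    "small": 0.10,
    "medium": 0.16,
    "large": 0.22,
}


class InfeasibleConfigurationError(ValueError):
    """Requested lesions cannot fit in the phantom foreground."""


@dataclass(frozen=True)
class PhantomConfig:
    """Controls one phantom image/mask pair.

    ``lesion_contrast`` is the peak intensity uplift of a lesion relative to
    the [0, 1] intensity scale; ``texture_scale`` is the correlation length
    (pixels) of the dominant parenchymal texture component.
    """

    image_side: int = 1024
    n_lesions: int = 1
    lesion_areas: tuple[float, ...] = (1000.0,)
    lesion_contrast: float | tuple[float, ...] = 0.18
    texture_scale: float = 32.0
    background_level: float = 0.35
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "lesion_areas", tuple(self.lesion_areas))
        if self.image_side < 256:
            raise ValueError("image_side must be >= 256")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if len(self.lesion_areas) != self.n_lesions:
            raise ValueError("lesion_areas must have n_lesions entries")
        if any(a < 1 for a in self.lesion_areas):
            raise ValueError("all lesion_areas must be >= 1")
        contrasts = self.contrasts
        if any(not 0.0 <= c <= 1.0 for c in contrasts):
            raise ValueError("lesion_contrast values must lie in [0, 1]")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")

    @property
    def contrasts(self) -> tuple[float, ...]:
        c = self.lesion_contrast
        if np.isscalar(c):
            return (float(c),) * self.n_lesions
        if len(c) != self.n_lesions:
            raise ValueError("lesion_contrast tuple must have n_lesions entries")
        return tuple(float(v) for v in c)


@dataclass
class ImagePair:
    """A grayscale raster and its aligned binary lesion mask."""

    id: str
    image: np.ndarray  # float32 in [0, 1]
    mask: np.ndarray   # uint8 in {0, 1}
    native_side: int
    lesion_area_native: int = field(default=-1)

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary")
        if self.lesion_area_native < 0:
            self.lesion_area_native = int(self.mask.sum())

    @property
    def lesion_area(self) -> int:
        """Positive pixels of the mask at its current resolution."""
        return int(self.mask.sum())


def _breast_foreground(side: int) -> np.ndarray:
    """Half-ellipse breast profile anchored to the left image edge."""
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    cy, a, b = side / 2.0, 0.46 * side, 0.78 * side
    return ((rr - cy) / a) ** 2 + (cc / b) ** 2 <= 1.0


def _texture(rng: np.random.Generator, side: int, scale: float) -> np.ndarray:
    """Multiscale smoothed-noise parenchyma texture, zero mean, std ~0.05."""
    tex = np.zeros((side, side))
    for s, w in ((scale, 1.0), (scale / 4.0, 0.5), (scale / 16.0, 0.25)):
        s = max(s, 0.8)
        layer = gaussian_filter(rng.standard_normal((side, side)), s)
        sd = layer.std()
        if sd > 0:
            tex += w * layer / sd
    return 0.05 * tex / np.sqrt((1.0 + 0.25 + 0.0625))


def _blob_mask(rng: np.random.Generator, area: float, side: int,
               center: tuple[float, float]) -> np.ndarray:
    """Rasterize an irregular star-shaped blob of ~``area`` pixels.

    The angular radius profile is ``r(t) = r0 * (1 + sum_k a_k cos(k t + p_k))``
    with low harmonics; ``r0`` is solved from area = 0.5 * ∫ r(t)^2 dt.
    """
    nharm = 4
    amps = rng.uniform(0.04, 0.12, size=nharm)
    phases = rng.uniform(0, 2 * np.pi, size=nharm)
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    shape = np.ones_like(theta)
    for k in range(nharm):
        shape += amps[k] * np.cos((k + 2) * theta + phases[k])
    mean_sq = np.mean(shape ** 2)
    r0 = np.sqrt(2.0 * area / (2.0 * np.pi * mean_sq))
    rmax = r0 * shape.max()
    cy, cx = center
    lo_r = max(int(np.floor(cy - rmax - 2)), 0)
    hi_r = min(int(np.ceil(cy + rmax + 2)), side)
    lo_c = max(int(np.floor(cx - rmax - 2)), 0)
    hi_c = min(int(np.ceil(cx + rmax + 2)), side)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c].astype(np.float64)
    dy, dx = rr - cy, cc - cx
    dist = np.hypot(dy, dx)
    ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    idx = np.minimum((ang / (2 * np.pi) * len(theta)).astype(int), len(theta) - 1)
    local = dist <= r0 * shape[idx]
    mask = np.zeros((side, side), dtype=bool)
    mask[lo_r:hi_r, lo_c:hi_c] = local
    return mask


def generate_phantom(config: PhantomConfig) -> ImagePair:
    """Render one phantom pair; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    side = config.image_side
    fg = _breast_foreground(side)
    fg_area = int(fg.sum())
    if sum(config.lesion_areas) > 0.5 * fg_area:
        raise InfeasibleConfigurationError(
            f"total lesion area {sum(config.lesion_areas):.0f} exceeds half the "
            f"foreground area ({fg_area})")
    image = np.full((side, side), 0.02)
    image[fg] = config.background_level
    image += _texture(rng, side, config.texture_scale) * fg
    mask = np.zeros((side, side), dtype=bool)
    # centers must keep the whole blob inside the foreground
    for area, contrast in zip(config.lesion_areas, config.contrasts):
        rmax_est = int(np.ceil(np.sqrt(area / np.pi) * 1.3)) + 3
        allowed = binary_erosion(fg, iterations=rmax_est) if rmax_est > 0 else fg
        cand = np.argwhere(allowed & ~mask)
        if len(cand) == 0:
            raise InfeasibleConfigurationError(
                f"no feasible center for a lesion of area {area:.0f}")
        blob = None
        for _ in range(50):
            cy, cx = cand[rng.integers(len(cand))]
            trial = _blob_mask(rng, area, side, (float(cy), float(cx)))
            if (trial & ~fg).sum() == 0 and (trial & mask).sum() == 0:
                blob = trial
                break
        if blob is None:
            raise InfeasibleConfigurationError(
                f"could not place a lesion of area {area:.0f} inside the foreground")
        # soft radial intensity profile, slightly feathered past the boundary
        dist_in = gaussian_filter(blob.astype(np.float64), np.sqrt(area / np.pi) * 0.35)
        prof = dist_in / max(dist_in.max(), 1e-12)
        image += contrast * prof
        mask |= blob
    image = np.clip(image, 0.0, 1.0)
    return ImagePair(
        id=f"phantom-{config.seed}",
        image=image.astype(np.float32),
        mask=mask.astype(np.uint8),
        native_side=side,
    )


def apportion(n: int, proportions: dict[str, float] | list[float]) -> dict[str, int] | list[int]:
    """Largest-remainder apportionment of ``n`` items over proportions."""
    keys = None
    if isinstance(proportions, dict):
        keys = list(proportions)
        props = np.array([proportions[k] for k in keys], dtype=np.float64)
    else:
        props = np.asarray(proportions, dtype=np.float64)
    if (props < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {props.sum()!r}")
    quotas = n * props
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    if keys is not None:
        return dict(zip(keys, counts.tolist()))
    return counts.tolist()


def generate_cohort(
    n_images: int,
    size_mix: dict[str, float] | tuple[float, float, float],
    area_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    image_side: int = 1024,
    reference_side: int | None = None,
    contrast_by_category: dict[str, float] | None = None,
    texture_scale: float = 32.0,
    background_level: float = 0.35,
) -> tuple[list[ImagePair], pd.DataFrame]:
    """Generate a one-lesion-per-image cohort with a controlled size mix.

    ``size_mix`` gives proportions over (small, medium, large); realized
    counts follow largest-remainder apportionment, so they match the mix
    exactly in counts. ``area_ranges`` are pixel-area sampling intervals per
    category, interpreted on the ``reference_side`` grid if given (areas are
    then scaled by ``(image_side / reference_side)**2`` when rendering at
    native resolution) — this lets category bounds defined at the model's
    224 grid drive a higher-resolution phantom.

    Returns the image pairs and a manifest with one row per image
    (id, area_px, category, seed); ``area_px`` is the *target* area on the
    reference grid, ``area_native`` the realized native-mask area.
    """
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    if not isinstance(size_mix, dict):
        size_mix = dict(zip(SIZE_CATEGORIES, size_mix))
    area_ranges = dict(DEFAULT_AREA_RANGES, **(area_ranges or {}))
    contrast = dict(DEFAULT_CONTRAST_BY_CATEGORY, **(contrast_by_category or {}))
    counts = apportion(n_images, size_mix)
    scale = 1.0 if reference_side is None else (image_side / reference_side) ** 2
    rng = np.random.default_rng(seed)
    pairs: list[ImagePair] = []
    rows: list[dict] = []
    i = 0
    for cat in SIZE_CATEGORIES:
        lo, hi = area_ranges[cat]
        for _ in range(counts.get(cat, 0)):
            area_ref = float(rng.uniform(lo, hi))
            pair_seed = int(rng.integers(0, 2 ** 31 - 1))
            cfg = PhantomConfig(
                image_side=image_side,
                n_lesions=1,
                lesion_areas=(area_ref * scale,),
                lesion_contrast=contrast[cat],
                texture_scale=texture_scale,
                background_level=background_level,
                seed=pair_seed,
            )
            pair = generate_phantom(cfg)
            pair.id = f"case-{i:04d}"
            pairs.append(pair)
            rows.append({
                "id": pair.id,
                "area_px": area_ref,
                "category": cat,
                "seed": pair_seed,
                "area_native": pair.lesion_area_native,
            })
            i += 1
    manifest = pd.DataFrame(rows, columns=["id", "area_px", "category", "seed",
                                           "area_native"])
    return pairs, manifest


def save_cohort(pairs: list[ImagePair], manifest: pd.DataFrame, outdir,
                bit_depth: int = 16) -> None:
    """Write ``images/``, ``masks/`` PNGs (matching basenames) + manifest.csv."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    if bit_depth == 8:
        dtype, scale = np.uint8, 255
    elif bit_depth == 16:
        dtype, scale = np.uint16, 65535
    else:
        raise ValueError("bit_depth must be 8 or 16")
    for p in pairs:
        iio.imwrite(outdir / "images" / f"{p.id}.png",
                    np.round(p.image * scale).astype(dtype))
        iio.imwrite(outdir / "masks" / f"{p.id}.png",
                    (p.mask.astype(np.uint32) * scale).astype(dtype))
    manifest.to_csv(outdir / "manifest.csv", index=False)


def load_cohort(outdir) -> tuple[list[ImagePair], pd.DataFrame]:
    """Read a cohort written by :func:`save_cohort`."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    pairs = []
    for pid in manifest["id"]:
        img = iio.imread(outdir / "images" / f"{pid}.png")
        msk = iio.imread(outdir / "masks" / f"{pid}.png")
        maxval = np.iinfo(img.dtype).max
        pairs.append(ImagePair(
            id=str(pid),
            image=(img.astype(np.float32) / maxval),
            mask=(msk > maxval // 2).astype(np.uint8),
            native_side=img.shape[0],
        ))
    return pairs, manifest
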