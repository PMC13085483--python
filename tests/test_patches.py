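"""Patch sampling: bbox/centroid math, coverage limits, splits, hybrid stream."""

import numpy as np
import pytest

from mammoseg.patches import (
    PatchSample,
    SamplerConfig,
    build_patch_dataset,
    extract_positive_patch,
    hybrid_batches,
    lesion_bbox,
    sample_negative_patches,
)
from mammoseg.phantom import ImagePair, PhantomConfig, generate_phantom

CFG = SamplerConfig(patch_side=224, seed=0)


def make_pair(side=512, lesion=None, pid="p"):
    img = np.full((side, side), 0.4, dtype=np.float32)
    msk = np.zeros((side, side), dtype=np.uint8)
    if lesion is not None:
        r0, r1, c0, c1 = lesion
        msk[r0:r1, c0:c1] = 1
        img[r0:r1, c0:c1] = 0.8
    return ImagePair(id=pid, image=img, mask=msk, native_side=side)


class TestLesionBBox:
    def test_single_pixel(self):
        m = np.zeros((32, 32), np.uint8)
        m[10, 20] = 1
        bb = lesion_bbox(m)
        assert (bb.rmin, bb.rmax, bb.cmin, bb.cmax) == (10, 10, 20, 20)
        assert bb.centroid == (10.0, 20.0)

    def test_square_centroid(self):
        m = np.zeros((16, 16), np.uint8)
        m[4:7, 7:10] = 1
        assert lesion_bbox(m).centroid == (5.0, 8.0)

    def test_empty_mask_sentinel(self):
        assert lesion_bbox(np.zeros((8, 8), np.uint8)) is None


class TestPositivePatch:
    def test_zero_jitter_centers_on_centroid(self):
        pair = make_pair(lesion=(250, 260, 250, 260))
        cfg = SamplerConfig(patch_side=224, centroid_jitter_frac=0.0)
        p = extract_positive_patch(pair, cfg, np.random.default_rng(0))
        # centroid of rows/cols 250..259 is 254.5; top-left = round(254.5 - 112)
        assert p.origin == (round(254.5 - 112), round(254.5 - 112))
        assert p.label == "positive"
        assert p.mask_crop.sum() > 0

    def test_corner_lesion_clamped_inside(self):
        pair = make_pair(lesion=(0, 8, 0, 8))
        p = extract_positive_patch(pair, CFG, np.random.default_rng(1))
        assert p.origin == (0, 0)
        assert p.mask_crop.sum() > 0

    def test_500_jittered_draws_all_contain_lesion(self):
        pair = make_pair(lesion=(200, 230, 300, 330))
        rng = np.random.default_rng(2)
        for _ in range(500):
            p = extract_positive_patch(pair, CFG, rng)
            assert p.mask_crop.sum() > 0

    def test_too_small_image_names_dimension(self):
        pair = make_pair(side=300, lesion=(10, 20, 10, 20))
        cfg = SamplerConfig(patch_side=512)
        with pytest.raises(ValueError, match="height"):
            extract_positive_patch(pair, cfg, np.random.default_rng(0))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_positive_patch(make_pair(), CFG, np.random.default_rng(0))


class TestNegativePatches:
    def test_two_per_positive_by_default(self):
        pair = make_pair(lesion=(100, 120, 100, 120))
        negs = sample_negative_patches(pair, CFG, np.random.default_rng(0))
        assert len(negs) == 2
        assert all(n.label == "negative" for n in negs)

    def test_coverage_always_below_limit(self, phantom_512):
        rng = np.random.default_rng(1)
        for _ in range(20):
            for n in sample_negative_patches(phantom_512, CFG, rng):
                assert n.coverage < 0.05

    def test_six_percent_coverage_window_rejected_by_construction(self):
        # a sample with >= 5% coverage cannot even be constructed
        m = np.zeros((224, 224), np.uint8)
        m[:56, :54] = 1  # 3024/50176 = 6.03%
        with pytest.raises(ValueError, match="coverage"):
            PatchSample(image_crop=np.zeros((224, 224), np.float32), mask_crop=m,
                        label="negative", source_id="x", origin=(0, 0))

    def test_all_zero_mask_any_window_qualifies(self):
        pair = make_pair()
        cfg = SamplerConfig(patch_side=224, restrict_to_foreground=False)
        negs = sample_negative_patches(pair, cfg, np.random.default_rng(0), n=5)
        assert len(negs) == 5
        assert all(n.coverage == 0.0 for n in negs)

    def test_budget_exhaustion_returns_fewer_not_mislabeled(self):
        # lesion covers nearly the whole image: no valid negative window
        pair = make_pair(side=256, lesion=(0, 250, 0, 256))
        cfg = SamplerConfig(patch_side=224, restrict_to_foreground=False,
                            attempt_budget=25)
        negs = sample_negative_patches(pair, cfg, np.random.default_rng(0))
        assert negs == []


class TestBuildPatchDataset:
    def _pairs(self, n, side=300, patch=224):
        out = []
        rng = np.random.default_rng(9)
        for i in range(n):
            r = int(rng.integers(40, side - 60))
            c = int(rng.integers(40, side - 60))
            out.append(make_pair(side=side, lesion=(r, r + 20, c, c + 20), pid=f"im{i}"))
        return out

    def test_ten_images_split_8_2_no_leakage(self):
        cfg = SamplerConfig(patch_side=224, seed=5)
        train, val = build_patch_dataset(self._pairs(10), cfg)
        train_ids = {p.source_id for p in train}
        val_ids = {p.source_id for p in val}
        assert len(train_ids) == 8 and len(val_ids) == 2
        assert train_ids.isdisjoint(val_ids)

    def test_rounding_of_train_fraction(self):
        cfg = SamplerConfig(patch_side=224, seed=5)
        train, val = build_patch_dataset(self._pairs(9), cfg)
        ids = {p.source_id for p in train}
        assert len(ids) == round(0.8 * 9)

    def test_three_patches_per_positive_when_feasible(self):
        cfg = SamplerConfig(patch_side=224, seed=5, restrict_to_foreground=False)
        train, val = build_patch_dataset(self._pairs(5), cfg)
        allp = train + val
        n_pos = sum(1 for p in allp if p.label == "positive")
        assert n_pos == 5
        assert len(allp) == 3 * n_pos

    def test_label_soundness_across_dataset(self):
        cfg = SamplerConfig(patch_side=224, seed=5)
        train, val = build_patch_dataset(self._pairs(6), cfg)
        for p in train + val:
            if p.label == "negative":
                assert p.coverage < 0.05
            else:
                assert p.mask_crop.sum() > 0

    def test_reproducible(self):
        cfg = SamplerConfig(patch_side=224, seed=5)
        a = build_patch_dataset(self._pairs(6), cfg)
        b = build_patch_dataset(self._pairs(6), cfg)
        for sa, sb in zip(a[0] + a[1], b[0] + b[1]):
            assert sa.origin == sb.origin and sa.source_id == sb.source_id

    def test_fewer_than_two_images_rejected(self):
        with pytest.raises(ValueError):
            build_patch_dataset(self._pairs(1), SamplerConfig())


class TestPatchPersistence:
    def test_roundtrip_preserves_labels_origins_masks(self, tmp_path):
        from mammoseg.patches import load_patch_dataset, save_patch_dataset

        pair = make_pair(lesion=(100, 130, 200, 230))
        rng = np.random.default_rng(0)
        patches = [extract_positive_patch(pair, CFG, rng)]
        patches += sample_negative_patches(pair, CFG, rng)
        save_patch_dataset(patches, tmp_path)
        loaded = load_patch_dataset(tmp_path)
        assert [p.label for p in loaded] == [p.label for p in patches]
        assert [p.origin for p in loaded] == [p.origin for p in patches]
        for a, b in zip(patches, loaded):
            assert np.array_equal(a.mask_crop, b.mask_crop)
            assert np.abs(a.image_crop - b.image_crop).max() < 1e-4


class TestHybridBatches:
    def _setup(self, side=64):
        pairs = [make_pair(side=side, lesion=(10, 20, 10, 20), pid=f"f{i}")
                 for i in range(4)]
        patch = PatchSample(image_crop=np.zeros((side, side), np.float32),
                            mask_crop=pairs[0].mask.copy(), label="positive",
                            source_id="f0", origin=(0, 0))
        return pairs, [patch]

    def test_prob_zero_all_full_images(self):
        pairs, pool = self._setup()
        cfg = SamplerConfig(patch_side=64, hybrid_substitution_prob=0.0)
        for x, y, prov in hybrid_batches(pairs, pool, cfg, np.random.default_rng(0),
                                         batch_size=4, n_batches=5):
            assert prov == ["full"] * 4

    def test_prob_one_all_patches(self):
        pairs, pool = self._setup()
        cfg = SamplerConfig(patch_side=64, hybrid_substitution_prob=1.0)
        for x, y, prov in hybrid_batches(pairs, pool, cfg, np.random.default_rng(0),
                                         batch_size=4, n_batches=5):
            assert prov == ["patch"] * 4

    def test_substitution_fraction_within_99pct_binomial_ci(self):
        pairs, pool = self._setup()
        cfg = SamplerConfig(patch_side=64, hybrid_substitution_prob=0.35)
        n_patch = total = 0
        gen = hybrid_batches(pairs, pool, cfg, np.random.default_rng(42),
                             batch_size=10, n_batches=1000)
        for _x, _y, prov in gen:
            n_patch += prov.count("patch")
            total += len(prov)
        assert total == 10_000
        assert 0.3366 <= n_patch / total <= 0.3634

    def test_empty_pool_with_positive_prob_rejected(self):
        pairs, _ = self._setup()
        cfg = SamplerConfig(patch_side=64, hybrid_substitution_prob=0.35)
        with pytest.raises(ValueError):
            next(hybrid_batches(pairs, [], cfg, np.random.default_rng(0)))

    def test_same_seed_identical_stream(self):
        pairs, pool = self._setup()
        cfg = SamplerConfig(patch_side=64, hybrid_substitution_prob=0.35)
        a = list(hybrid_batches(pairs, pool, cfg, np.random.default_rng(7), n_batches=3))
        b = list(hybrid_batches(pairs, pool, cfg, np.random.default_rng(7), n_batches=3))
        for (xa, ya, pa), (xb, yb, pb) in zip(a, b):
            assert np.array_equal(xa, xb) and pa == pb
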