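"""Preprocessing: CLAHE contract, binarization, resizing, augmentation."""

import numpy as np
import pytest
from skimage import exposure

from mammoseg.phantom import ImagePair
from mammoseg.preprocess import (
    AugmentConfig,
    PreprocessConfig,
    augment,
    binarize_mask,
    dataset_stats,
    normalize_and_enhance,
    preprocess_pair,
    resize_pair,
)


class TestNormalizeAndEnhance:
    def test_default_config_matches_published_settings(self):
        cfg = PreprocessConfig()
        assert cfg.clahe_clip_limit == 2.0
        assert cfg.clahe_tile_grid == 8
        assert cfg.target_side == 224
        assert cfg.mask_threshold == 0.5

    def test_flat_field_maps_to_zeros(self):
        out = normalize_and_enhance(np.full((64, 64), 0.7))
        assert np.array_equal(out, np.zeros((64, 64), np.float32))

    def test_output_range_and_shape(self, rng):
        img = rng.random((100, 140))
        out = normalize_and_enhance(img)
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_checkerboard_matches_reference_clahe(self):
        img = np.tile(np.array([[0.0, 1.0], [1.0, 0.0]]), (112, 112))
        cfg = PreprocessConfig()
        out = normalize_and_enhance(img, cfg)
        kernel = tuple(s // cfg.clahe_tile_grid for s in img.shape)
        ref = exposure.equalize_adapthist(img, kernel_size=kernel,
                                          clip_limit=cfg.clahe_clip_limit / 256,
                                          nbins=256)
        assert np.abs(out - ref).max() < 1e-6
        assert out.min() == 0.0 and out.max() == 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_enhance(np.array([[np.nan, 1.0]]))


class TestBinarizeMask:
    def test_strict_greater_at_threshold(self):
        vals = np.array([0.0, 0.49, 0.5, 0.51, 1.0])
        assert binarize_mask(vals, 0.5).tolist() == [0, 0, 0, 1, 1]

    def test_all_zero_and_idempotence(self, rng):
        z = np.zeros((8, 8))
        assert binarize_mask(z).sum() == 0
        m = (rng.random((8, 8)) > 0.5).astype(float)
        assert np.array_equal(binarize_mask(m), m.astype(np.uint8))
        assert np.array_equal(binarize_mask(binarize_mask(m)), binarize_mask(m))


class TestResizePair:
    def test_all_zero_mask_stays_empty(self):
        pair = ImagePair(id="z", image=np.zeros((1024, 1024), np.float32),
                         mask=np.zeros((1024, 1024), np.uint8), native_side=1024)
        out = resize_pair(pair, 224)
        assert out.mask.sum() == 0
        assert out.image.shape == (224, 224)

    def test_area_scaling_of_square_lesion(self, square_pair):
        out = resize_pair(square_pair, 224)
        expected = 100 * 100 * (224 / 1000) ** 2
        assert abs(out.lesion_area - expected) <= 0.1 * expected
        assert out.lesion_area_native == 10000  # native area preserved

    def test_mask_binary_after_resize(self, phantom_512):
        out = resize_pair(phantom_512, 224)
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_linear_reduction_factor(self):
        from mammoseg.evaluate import resolution_analysis

        fold, _ = resolution_analysis(4000, 224, 1)
        assert fold == pytest.approx(4000 / 224)

    def test_tiny_target_rejected(self, square_pair):
        with pytest.raises(ValueError):
            resize_pair(square_pair, 16)


class TestAugment:
    def test_zero_probability_is_identity(self, phantom_512, rng):
        cfg = AugmentConfig(p_apply=0.0)
        out = augment(phantom_512, cfg, rng)
        assert np.array_equal(out.image, phantom_512.image)
        assert np.array_equal(out.mask, phantom_512.mask)

    def test_reproducible_given_seed(self, phantom_512):
        a = augment(phantom_512, AugmentConfig(), np.random.default_rng(3))
        b = augment(phantom_512, AugmentConfig(), np.random.default_rng(3))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_hflip_involution(self, phantom_512):
        flipped = ImagePair(id="f", image=phantom_512.image[:, ::-1].copy(),
                            mask=phantom_512.mask[:, ::-1].copy(),
                            native_side=phantom_512.native_side)
        back = ImagePair(id="b", image=flipped.image[:, ::-1].copy(),
                         mask=flipped.mask[:, ::-1].copy(),
                         native_side=flipped.native_side)
        assert np.array_equal(back.image, phantom_512.image)

    def test_geometric_lockstep_mask_as_image(self, phantom_512):
        # transform the mask through the image channel: pixels stay aligned
        cfg = AugmentConfig(elastic=False, clahe_jitter=False, p_apply=1.0)
        probe = ImagePair(id="p", image=phantom_512.mask.astype(np.float32),
                          mask=phantom_512.mask.copy(),
                          native_side=phantom_512.native_side)
        out = augment(probe, cfg, np.random.default_rng(4))
        assert np.array_equal(binarize_mask(out.image, 0.5), out.mask)

    @pytest.mark.parametrize("seed", range(30))
    def test_lesion_always_preserved(self, phantom_small_lesion, seed):
        out = augment(phantom_small_lesion, AugmentConfig(),
                      np.random.default_rng(seed))
        assert out.lesion_area > 0

    def test_mask_stays_binary(self, phantom_512, rng):
        out = augment(phantom_512, AugmentConfig(p_apply=1.0), rng)
        assert set(np.unique(out.mask)) <= {0, 1}


class TestDatasetStats:
    def test_hand_counts(self):
        img = np.zeros((100, 100), np.float32)
        msk = np.zeros((100, 100), np.uint8)
        msk[:5, :10] = 1  # 50 positive pixels
        pair = ImagePair(id="a", image=img, mask=msk, native_side=100)
        stats = dataset_stats([pair])
        assert stats["positive_pixels"] == 50
        assert stats["lesion_to_background_ratio"] == pytest.approx(50 / 9950)

    def test_two_image_totals(self):
        def mk(n, i):
            m = np.zeros((100, 100), np.uint8)
            m.flat[:n] = 1
            return ImagePair(id=str(i), image=np.zeros((100, 100), np.float32),
                             mask=m, native_side=100)

        stats = dataset_stats([mk(100, 0), mk(300, 1)])
        assert stats["per_image_areas"] == [100, 300]
        assert stats["positive_pixels"] == 400

    def test_all_zero_masks_ratio_zero(self):
        pair = ImagePair(id="z", image=np.zeros((10, 10), np.float32),
                         mask=np.zeros((10, 10), np.uint8), native_side=10)
        assert dataset_stats([pair])["lesion_to_background_ratio"] == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            dataset_stats([])


def test_preprocess_pair_end_to_end(phantom_512):
    out = preprocess_pair(phantom_512)
    assert out.image.shape == (224, 224)
    assert set(np.unique(out.mask)) <= {0, 1}
    assert out.lesion_area_native == phantom_512.lesion_area_native
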