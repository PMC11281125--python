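"""Preprocessing chain: background mask, mean fill, CLAHE, augmentation."""

import numpy as np
import pytest

from fundustruct.images import BinaryMask, FundusImage, GrayImage
from fundustruct.preprocess import (DegenerateInputError, PreprocessParams,
                                    clahe_on_luminance, compute_background_mask,
                                    fill_background_mean, preprocess_fundus,
                                    reapply_black_background, rotation_augment,
                                    split_train_val, to_classifier_input)


def gray_image(value, size=64):
    return FundusImage(np.full((size, size, 3), value, dtype=np.uint8))


class TestBackgroundMask:
    def test_threshold_is_strict(self):
        """Gray 41 is foreground, gray 39 background, at the default 40."""
        arr = np.zeros((64, 64, 3), dtype=np.uint8)
        arr[0, 0] = 41
        arr[0, 1] = 39
        mask = compute_background_mask(FundusImage(arr))
        assert mask.pixels[0, 0] == 1 and mask.pixels[0, 1] == 0

    def test_all_black_image_is_all_background(self):
        assert compute_background_mask(gray_image(0)).pixels.sum() == 0

    def test_disc_area_matches_exhaustive_count(self):
        """Foreground of a white disc equals a brute-force pixel scan."""
        arr = np.zeros((512, 512, 3), dtype=np.uint8)
        rows, cols = np.ogrid[:512, :512]
        inside = (rows - 256) ** 2 + (cols - 256) ** 2 <= 100 ** 2
        arr[inside] = 255
        mask = compute_background_mask(FundusImage(arr))
        assert mask.pixels.sum() == int(inside.sum())
        np.testing.assert_array_equal(mask.pixels.astype(bool), inside)

    def test_monotone_in_threshold(self, rng):
        """Raising the threshold never adds foreground pixels."""
        img = FundusImage(rng.integers(0, 256, (64, 64, 3), dtype=np.uint8))
        prev = compute_background_mask(img, PreprocessParams(background_threshold=10))
        for t in (40, 80, 160, 250):
            cur = compute_background_mask(img, PreprocessParams(background_threshold=t))
            assert np.all(cur.pixels <= prev.pixels)
            prev = cur


class TestFillBackgroundMean:
    def test_constant_foreground_fills_background(self):
        arr = np.zeros((64, 64, 3), dtype=np.uint8)
        arr[:32] = (200, 100, 50)
        mask = BinaryMask((np.arange(64) < 32)[:, None] * np.ones(64, dtype=np.uint8))
        out = fill_background_mean(FundusImage(arr), mask)
        assert np.all(out.pixels[40, 40] == (200, 100, 50))

    def test_two_pixel_hand_mean(self):
        arr = np.zeros((64, 64, 3), dtype=np.uint8)
        arr[0, 0] = (10, 20, 30)
        arr[0, 1] = (30, 40, 50)
        mask_arr = np.zeros((64, 64), dtype=np.uint8)
        mask_arr[0, :2] = 1
        out = fill_background_mean(FundusImage(arr), BinaryMask(mask_arr))
        assert tuple(out.pixels[50, 50]) == (20, 30, 40)

    def test_all_foreground_is_identity(self, rng):
        arr = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        out = fill_background_mean(FundusImage(arr), BinaryMask(np.ones((64, 64), dtype=np.uint8)))
        np.testing.assert_array_equal(out.pixels, arr)

    def test_no_foreground_raises(self):
        with pytest.raises(DegenerateInputError):
            fill_background_mean(gray_image(100), BinaryMask(np.zeros((64, 64), dtype=np.uint8)))

    def test_foreground_untouched(self, rng):
        arr = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        mask_arr = (rng.random((64, 64)) < 0.5).astype(np.uint8)
        mask_arr[0, 0] = 1
        out = fill_background_mean(FundusImage(arr), BinaryMask(mask_arr))
        fg = mask_arr.astype(bool)
        np.testing.assert_array_equal(out.pixels[fg], arr[fg])


class TestClahe:
    def test_flat_field_stays_flat(self):
        out = clahe_on_luminance(gray_image(120, size=128))
        for ch in range(3):
            assert np.ptp(out.pixels[:, :, ch]) <= 1

    def test_contrast_expansion_on_low_contrast_ramp(self, rng):
        """A dim noisy ramp gains luminance spread after equalization."""
        from skimage import color
        base = np.linspace(90, 130, 128)[None, :] * np.ones((128, 1))
        noisy = np.clip(base + rng.normal(0, 2, base.shape), 0, 255).astype(np.uint8)
        img = FundusImage(np.stack([noisy] * 3, axis=-1))
        out = clahe_on_luminance(img)
        l_in = color.rgb2lab(img.pixels / 255.0)[:, :, 0]
        l_out = color.rgb2lab(out.pixels / 255.0)[:, :, 0]
        assert l_out.std() >= l_in.std()

    def test_shape_and_range_contract(self, rng):
        img = FundusImage(rng.integers(0, 256, (96, 128, 3), dtype=np.uint8))
        out = clahe_on_luminance(img)
        assert out.pixels.shape == (96, 128, 3)
        assert out.pixels.dtype == np.uint8


class TestComposition:
    def test_reapply_black_background(self, rng):
        arr = rng.integers(1, 256, (64, 64, 3), dtype=np.uint8)
        ones = BinaryMask(np.ones((64, 64), dtype=np.uint8))
        zeros = BinaryMask(np.zeros((64, 64), dtype=np.uint8))
        np.testing.assert_array_equal(reapply_black_background(FundusImage(arr), ones).pixels, arr)
        assert reapply_black_background(FundusImage(arr), zeros).pixels.sum() == 0

    def test_preprocess_equals_manual_composition(self, rng):
        arr = rng.integers(0, 256, (128, 128, 3), dtype=np.uint8)
        arr[:40] = 0   # black band to give the mask structure
        img = FundusImage(arr)
        params = PreprocessParams()
        out, mask = preprocess_fundus(img, params)
        manual_mask = compute_background_mask(img, params)
        manual = reapply_black_background(
            clahe_on_luminance(fill_background_mean(img, manual_mask), params), manual_mask)
        np.testing.assert_array_equal(out.pixels, manual.pixels)
        np.testing.assert_array_equal(mask.pixels, manual_mask.pixels)
        assert np.all(out.pixels[mask.pixels == 0] == 0)

    def test_no_foreground_after_thresholding_raises(self):
        with pytest.raises(DegenerateInputError):
            preprocess_fundus(gray_image(100), PreprocessParams(background_threshold=254))

    def test_background_stays_background_when_rerun(self, rng):
        """The output's background mask contains the original background."""
        arr = rng.integers(0, 256, (128, 128, 3), dtype=np.uint8)
        arr[:40] = 0
        img = FundusImage(arr)
        out, mask = preprocess_fundus(img)
        mask2 = compute_background_mask(out)
        assert np.all(mask2.pixels[mask.pixels == 0] == 0)


class TestClassifierInput:
    def test_resizes_color_to_single_channel_64(self, rng):
        img = FundusImage(rng.integers(0, 256, (512, 512, 3), dtype=np.uint8))
        out = to_classifier_input(img)
        assert out.pixels.shape == (64, 64)

    def test_identity_resize(self, rng):
        arr = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        np.testing.assert_array_equal(to_classifier_input(GrayImage(arr)).pixels, arr)

    def test_flat_field_resize_preserves_value(self):
        out = to_classifier_input(GrayImage(np.full((128, 128), 77, dtype=np.uint8)))
        assert np.all(out.pixels == 77)


class TestRotationAugment:
    def test_paper_scale_counts(self, rng):
        imgs = [GrayImage(rng.integers(0, 256, (64, 64), dtype=np.uint8)) for _ in range(30)]
        assert len(rotation_augment(imgs, 10)) == 1080
        assert len(rotation_augment(imgs[:2], 10)) == 72

    def test_step_360_is_identity(self, rng):
        imgs = [GrayImage(rng.integers(0, 256, (64, 64), dtype=np.uint8)) for _ in range(5)]
        out = rotation_augment(imgs, 360)
        assert len(out) == 5
        for a, b in zip(imgs, out):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("step", [10, 30, 90, 360])
    def test_count_law(self, step, rng):
        imgs = [GrayImage(rng.integers(0, 256, (64, 64), dtype=np.uint8)) for _ in range(3)]
        assert len(rotation_augment(imgs, step)) == 3 * 360 // step

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            rotation_augment([], 7)

    def test_right_angle_rotations_lossless(self, rng):
        """Four successive 90-degree rotations reproduce the raster exactly."""
        img = GrayImage(rng.integers(0, 256, (64, 64), dtype=np.uint8))
        out = rotation_augment([img], 90)
        assert len(out) == 4
        from fundustruct.preprocess import rotate_raster
        x = img
        for _ in range(4):
            x = rotate_raster(x, 90)
        np.testing.assert_array_equal(x.pixels, img.pixels)


class TestSplit:
    def test_partition_counts(self):
        train, val = split_train_val(list(range(32)), n_val=2, seed=3)
        assert len(train) == 30 and len(val) == 2
        assert sorted(train + val) == list(range(32))
        assert not set(train) & set(val)

    def test_same_seed_same_split(self):
        assert split_train_val(list(range(20)), 4, seed=9) == split_train_val(list(range(20)), 4, seed=9)

    def test_oversized_val_rejected(self):
        with pytest.raises(ValueError):
            split_train_val([1, 2], n_val=2, seed=0)
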