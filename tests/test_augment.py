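"""Augmentation conservation laws and geometry pipeline contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliofusion.augment import (AugmentConfig, crop, cyclic_shift,
                                eval_transform, flip, lgg_train_transform,
                                resize, rotate, salt_pepper)
from gliofusion.errors import ValidationError


def _image(h=24, w=24, c=4, seed=0):
    return np.random.default_rng(seed).normal(size=(c, h, w)).astype(np.float32)


class TestCrop:
    def test_center_crop_240_to_160_offset_40(self):
        img = _image(240, 240)
        out = crop(img, 160, "center")
        assert np.array_equal(out, img[:, 40:200, 40:200])

    def test_crop_to_own_size_is_identity(self):
        img = _image()
        assert np.array_equal(crop(img, 24, "center"), img)

    def test_random_crop_reproducible(self):
        img = _image(224, 224)
        a = crop(img, 160, "random", np.random.default_rng(5))
        b = crop(img, 160, "random", np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_oversized_crop_rejected(self):
        with pytest.raises(ValidationError):
            crop(_image(), 100, "center")


class TestResize:
    def test_same_size_is_identity(self):
        img = _image()
        assert np.abs(resize(img, 24) - img).max() < 1e-6

    def test_constant_image_stays_constant(self):
        img = np.full((4, 32, 32), 2.5, np.float32)
        assert np.abs(resize(img, 64) - 2.5).max() < 1e-5

    def test_round_trip_error_small_on_smooth_images(self):
        """224 -> 448 -> 224 on a smooth phantom: mean abs error below 2% of
        the dynamic range (frozen from a one-off measurement)."""
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(_image(224, 224), (0, 3, 3))
        back = resize(resize(img, 448), 224)
        mae = np.abs(back - img).mean() / (img.max() - img.min())
        assert mae < 0.02


class TestFlip:
    def test_double_flip_identity(self):
        img = _image()
        for axis in ("horizontal", "vertical"):
            assert np.array_equal(flip(flip(img, axis), axis), img)

    def test_known_two_by_two_mirror(self):
        img = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert np.array_equal(flip(img, "horizontal"),
                              np.array([[[2.0, 1.0], [4.0, 3.0]]]))
        assert np.array_equal(flip(img, "vertical"),
                              np.array([[[3.0, 4.0], [1.0, 2.0]]]))

    def test_preserves_pixel_multiset(self):
        img = _image()
        out = flip(img, "horizontal")
        assert np.array_equal(np.sort(out.ravel()), np.sort(img.ravel()))


class TestCyclicShift:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(dx=st.integers(-40, 40), dy=st.integers(-40, 40))
    def test_shift_then_inverse_is_identity(self, dx, dy):
        img = _image(16, 16)
        assert np.array_equal(cyclic_shift(cyclic_shift(img, dx, dy), -dx, -dy),
                              img)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(dx=st.integers(-200, 200), dy=st.integers(-200, 200))
    def test_conserves_pixel_multiset_exactly(self, dx, dy):
        img = _image(16, 16)
        out = cyclic_shift(img, dx, dy)
        assert np.array_equal(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_zero_shift_identity_and_pixel_mapping(self):
        img = _image(8, 8)
        assert np.array_equal(cyclic_shift(img, 0, 0), img)
        out = cyclic_shift(img, 3, 2)
        assert out[0, (0 + 2) % 8, (0 + 3) % 8] == img[0, 0, 0]


class TestRotate:
    def test_zero_rotation_identity(self):
        img = _image()
        assert np.abs(rotate(img, 0.0) - img).max() < 1e-6

    def test_full_turn_near_identity(self):
        img = _image()
        assert np.abs(rotate(img, 360.0) - img).max() < 1e-6

    def test_quarter_turn_matches_lattice_rotation(self):
        img = _image(32, 32)
        assert np.abs(rotate(img, 90.0) - np.rot90(img, 1, axes=(1, 2))).max() < 1e-6


class TestSaltPepper:
    def test_zero_fraction_identity(self):
        img = _image()
        assert np.array_equal(salt_pepper(img, 0.0, np.random.default_rng(0)), img)

    def test_full_fraction_extremes_everywhere(self):
        img = _image(16, 16)
        out = salt_pepper(img, 1.0, np.random.default_rng(0))
        for ch in range(4):
            assert np.all((out[ch] == 0.0) | (out[ch] == img[ch].max()))

    def test_exact_corruption_count_on_160(self):
        img = np.full((4, 160, 160), 0.5, np.float32)
        out = salt_pepper(img, 0.02, np.random.default_rng(1))
        n_pepper = int((out[0] == 0.0).sum())
        n_salt_positions = 512 - n_pepper  # salt equals the max 0.5, invisible
        assert n_pepper + n_salt_positions == round(0.02 * 160 * 160) == 512
        # on a non-constant image all 512 corrupted positions are visible
        img2 = _image(160, 160) + 10.0
        out2 = salt_pepper(img2, 0.02, np.random.default_rng(1))
        assert int((out2[0] != img2[0]).sum()) == 512

    def test_positions_shared_across_channels(self):
        img = _image(32, 32) + 10.0
        out = salt_pepper(img, 0.1, np.random.default_rng(2))
        changed = out != img
        for ch in range(1, 4):
            assert np.array_equal(changed[0], changed[ch])


class TestChannelConsistency:
    @pytest.mark.parametrize("transform", [
        lambda im, rng: flip(im, "horizontal"),
        lambda im, rng: cyclic_shift(im, 5, -3),
        lambda im, rng: rotate(im, 37.0),
        lambda im, rng: crop(resize(im, 48), 24, "random", rng),
    ])
    def test_same_geometric_map_on_every_channel(self, transform):
        """A watermark pattern replicated on all channels must stay identical
        across channels after any geometric transform."""
        base = _image(24, 24, c=1)[0]
        img = np.stack([base] * 4)
        out = transform(img, np.random.default_rng(0))
        for ch in range(1, 4):
            assert np.array_equal(out[0], out[ch])


class TestPipelines:
    def test_lgg_transform_output_shape_and_reproducibility(self):
        raw = _image(64, 64)
        cfg = AugmentConfig()
        a = lgg_train_transform(raw, cfg, np.random.default_rng(9))
        b = lgg_train_transform(raw, cfg, np.random.default_rng(9))
        assert a.shape == (4, 160, 160)
        assert np.array_equal(a, b)

    def test_all_toggles_off_geometry_only_deterministic(self):
        raw = _image(240, 240)
        cfg = AugmentConfig.disabled()
        a = lgg_train_transform(raw, cfg, np.random.default_rng(3))
        b = lgg_train_transform(raw, cfg, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_eval_transform_center_crops_240(self):
        raw = _image(240, 240)
        out = eval_transform(raw)
        assert np.array_equal(out, raw[:, 40:200, 40:200])
        assert np.array_equal(eval_transform(out), out)  # idempotent at 160

    def test_eval_transform_pads_undersized_slices(self):
        raw = _image(150, 150)
        out = eval_transform(raw)
        assert out.shape == (4, 160, 160)
        assert np.all(out[:, :5, :] == 0) and np.all(out[:, -5:, :] == 0)
        assert np.all(out[:, :, :5] == 0) and np.all(out[:, :, -5:] == 0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            AugmentConfig(rotation_range_deg=(-90.0, 180.0))
        with pytest.raises(ValidationError):
            AugmentConfig(salt_pepper_fraction=1.5)
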