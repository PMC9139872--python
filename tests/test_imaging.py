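"""Image I/O, color-card correction, shielding, and brightness operations."""

import imageio.v3 as iio
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ulcerquant import (
    ColorCardMeasurement,
    RGBImage,
    adjust_brightness,
    correct_with_card,
    load_image,
    save_image,
    shield_channel,
    suppress_low_red,
)
from ulcerquant.imaging import CalibrationError, fit_card_transform

from conftest import random_image


class TestLoadImage:
    def test_png_roundtrip_is_lossless(self, tmp_path):
        arr = np.full((2, 2, 3), (10, 20, 30), dtype=np.uint8)
        path = tmp_path / "t.png"
        iio.imwrite(path, arr)
        img = load_image(path)
        assert np.array_equal(img.pixels, arr)

    def test_16bit_tiff_full_scale_maps_to_255(self, tmp_path):
        arr = np.full((2, 2, 3), 65535, dtype=np.uint16)
        path = tmp_path / "t.tiff"
        iio.imwrite(path, arr)
        assert load_image(path).pixels.max() == 255
        assert load_image(path).pixels.min() == 255

    def test_grayscale_is_replicated_to_three_channels(self, tmp_path):
        arr = np.full((3, 3), 128, dtype=np.uint8)
        path = tmp_path / "g.png"
        iio.imwrite(path, arr)
        img = load_image(path)
        assert img.pixels.shape == (3, 3, 3)
        assert (img.pixels == 128).all()

    def test_alpha_channel_is_dropped(self, tmp_path):
        arr = np.full((2, 2, 4), (5, 6, 7, 200), dtype=np.uint8)
        path = tmp_path / "a.png"
        iio.imwrite(path, arr)
        img = load_image(path)
        assert img.pixels.shape == (2, 2, 3)
        assert tuple(img.pixels[0, 0]) == (5, 6, 7)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_image(tmp_path / "absent.png")

    def test_save_load_roundtrip(self, tmp_path, rng):
        img = random_image(rng)
        save_image(img, tmp_path / "r.png")
        assert load_image(tmp_path / "r.png") == img


class TestRGBImageInvariants:
    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            RGBImage(np.zeros((4, 4), dtype=np.uint8))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            RGBImage(np.full((2, 2, 3), 300))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            RGBImage(np.zeros((0, 2, 3), dtype=np.uint8))


def _card(values):
    return ColorCardMeasurement(np.asarray(values, dtype=float))


class TestCardCorrection:
    def test_identity_when_measured_equals_reference(self, rng):
        img = random_image(rng)
        card = _card([[10, 20, 30], [100, 110, 120], [200, 210, 220]])
        assert correct_with_card(img, card, card) == img

    def test_gain_two_analytic_case(self):
        ref = _card([[100, 50, 25], [200, 100, 50]])
        measured = _card([[50, 25, 12.5], [100, 50, 25]])
        img = RGBImage(np.full((1, 1, 3), (100, 50, 25), dtype=np.uint8))
        out = correct_with_card(img, measured, ref)
        assert tuple(out.pixels[0, 0]) == (200, 100, 50)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_random_affine_transform(self, seed):
        """Closed-form two-parameter least squares recovers gain/offset."""
        rng = np.random.default_rng(seed)
        measured = rng.uniform(45, 110, size=(6, 3))  # keeps ref inside [0,255]
        gain = rng.uniform(0.5, 2.0, size=3)
        offset = rng.uniform(-20, 20, size=3)
        ref_patches = gain * measured + offset
        gains, offsets = fit_card_transform(_card(measured), _card(ref_patches))
        assert np.allclose(gains, gain, atol=1e-6)
        assert np.allclose(offsets, offset, atol=1e-6)

    def test_degenerate_card_raises(self, rng):
        img = random_image(rng)
        flat = _card([[50, 50, 50], [50, 50, 50]])
        ref = _card([[10, 10, 10], [200, 200, 200]])
        with pytest.raises(CalibrationError):
            correct_with_card(img, flat, ref)

    def test_patch_count_mismatch_raises(self, rng):
        img = random_image(rng)
        a = _card([[10, 10, 10], [200, 200, 200]])
        b = _card([[10, 10, 10], [100, 100, 100], [200, 200, 200]])
        with pytest.raises(ValueError):
            correct_with_card(img, a, b)


class TestShielding:
    @pytest.mark.parametrize(
        "color,pixel,expected",
        [
            ("red", (200, 150, 100), (200, 0, 0)),
            ("red", (0, 255, 0), (0, 0, 0)),  # green marker hidden by red film
            ("blue", (0, 0, 255), (0, 0, 255)),
            ("green", (30, 40, 50), (0, 40, 0)),
        ],
    )
    def test_film_passes_own_channel_and_hides_others(self, color, pixel, expected):
        img = RGBImage(np.full((1, 1, 3), pixel, dtype=np.uint8))
        assert tuple(shield_channel(img, color).pixels[0, 0]) == expected

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from(["red", "green", "blue"]))
    def test_shielding_is_idempotent(self, seed, color):
        img = random_image(np.random.default_rng(seed), 8, 8)
        once = shield_channel(img, color)
        assert shield_channel(once, color) == once


class TestLowRedSuppression:
    def test_below_threshold_unified_with_background(self):
        img = RGBImage(np.full((1, 1, 3), (30, 80, 90), dtype=np.uint8))
        out, mask = suppress_low_red(img, 50)
        assert tuple(out.pixels[0, 0]) == (0, 0, 0)
        assert not mask[0, 0]

    def test_above_threshold_unchanged_and_included(self):
        img = RGBImage(np.full((1, 1, 3), (200, 80, 90), dtype=np.uint8))
        out, mask = suppress_low_red(img, 50)
        assert tuple(out.pixels[0, 0]) == (200, 80, 90)
        assert mask[0, 0]

    def test_threshold_extremes(self, rng):
        img = random_image(rng)
        _, mask0 = suppress_low_red(img, 0)
        assert mask0.all()
        _, mask256 = suppress_low_red(img, 256)
        assert not mask256.any()

    def test_recovers_ground_truth_lesion_mask(self):
        """Background red 80 vs lesion red 220, threshold 150: per-pixel match."""
        from ulcerquant.synthetic import LesionSpec, make_gastric_image

        spec = LesionSpec(
            background_rgb=(80, 145, 150),
            lesion_red=220,
            noise_sd=0.0,
            area_fraction_target=0.05,
            seed=3,
        )
        image, truth = make_gastric_image(spec)
        _, mask = suppress_low_red(image, 150)
        assert np.array_equal(mask, truth)


class TestBrightness:
    def test_level_100_is_identity(self, rng):
        img = random_image(rng)
        assert adjust_brightness(img, 100) == img

    def test_level_200_halves(self):
        img = RGBImage(np.full((1, 1, 3), 100, dtype=np.uint8))
        assert adjust_brightness(img, 200).pixels[0, 0, 0] == 50

    def test_level_50_doubles_and_clips(self):
        img = RGBImage(np.full((1, 1, 3), 200, dtype=np.uint8))
        assert adjust_brightness(img, 50).pixels[0, 0, 0] == 255

    def test_nonpositive_level_rejected(self, rng):
        img = random_image(rng)
        with pytest.raises(ValueError):
            adjust_brightness(img, 0)

    def test_bright_then_dark_is_identity_without_clipping(self):
        # values <= 127 never clip at level 50
        vals = np.arange(0, 128, dtype=np.uint8).reshape(8, 16)
        img = RGBImage(np.stack([vals] * 3, axis=-1))
        roundtrip = adjust_brightness(adjust_brightness(img, 50), 200)
        assert roundtrip == img
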