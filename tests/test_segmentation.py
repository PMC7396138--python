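"""Focus crop, contrast stretch, thresholding and classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fabriscope.errors import NoThresholdError, TooSmallRegionError
from fabriscope.image import FabricImage
from fabriscope.segmentation import (
    classify_pixels,
    compute_threshold,
    crop_focus_region,
    segment,
    stretch_contrast,
)
from fabriscope.synthetic import WeaveParams, generate_weave_image

from conftest import brute_force_otsu, geometric_pore_truth


def _image(arr) -> FabricImage:
    return FabricImage(np.asarray(arr, dtype=np.uint8))


class TestCropFocusRegion:
    def test_fraction_one_is_identity(self):
        img = _image(np.arange(100).reshape(10, 10) % 256)
        out = crop_focus_region(img, 1.0)
        assert np.array_equal(out.pixels, img.pixels)

    def test_centered_sixty_percent_crop(self):
        img = _image(np.zeros((100, 100)))
        out = crop_focus_region(img, 0.6)
        assert out.shape == (60, 60)

    def test_metadata_preserved(self):
        img = FabricImage(
            np.zeros((64, 64), dtype=np.uint8), pixel_scale=1.5, mask_id="M1",
            layer="L1", region_index=3,
        )
        out = crop_focus_region(img, 0.5)
        assert (out.pixel_scale, out.mask_id, out.layer, out.region_index) == (
            1.5, "M1", "L1", 3,
        )

    def test_too_small_crop_rejected(self):
        with pytest.raises(TooSmallRegionError):
            crop_focus_region(_image(np.zeros((20, 20))), 0.5)

    def test_crop_beats_full_frame_on_vignetted_weave(self):
        # vignetting darkens edge pores toward yarn intensity; only the
        # central in-focus region gives a faithful cover factor
        params = WeaveParams(
            warp_pitch=60, weft_pitch=60, warp_width=30, weft_width=30,
            image_size=(800, 800), vignette_strength=0.75, blur_sigma_px=1.0,
        )
        image, truth = generate_weave_image(params)

        def measured_cover(fraction):
            mask = segment(image, focus_fraction=fraction)
            return 100.0 * mask.n_yarn / mask.n_total

        err_full = abs(measured_cover(1.0) - truth.true_cover_factor)
        err_crop = abs(measured_cover(0.6) - truth.true_cover_factor)
        assert err_crop < err_full


class TestStretchContrast:
    def test_full_range_image_unchanged(self):
        img = _image(np.linspace(0, 255, 256).reshape(16, 16))
        out = stretch_contrast(img, 0, 100)
        assert np.array_equal(out.pixels, img.pixels)

    def test_constant_image_flagged_unchanged(self):
        img = _image(np.full((32, 32), 7))
        out = stretch_contrast(img)
        assert np.array_equal(out.pixels, img.pixels)
        assert out.meta.get("constant_image") is True

    def test_idempotent_up_to_quantization(self, rng):
        img = _image(rng.normal(128, 20, (64, 64)).clip(0, 255))
        once = stretch_contrast(img, 1, 99)
        twice = stretch_contrast(once, 1, 99)
        assert np.abs(twice.pixels.astype(int) - once.pixels.astype(int)).max() <= 2

    def test_low_contrast_weave_recovered(self, rng):
        # pore 120 vs yarn 100 barely separated; stretching restores a
        # clean Otsu split against the geometric truth
        params = WeaveParams(
            warp_pitch=50, weft_pitch=50, warp_width=25, weft_width=25,
            image_size=(600, 600), yarn_intensity=100, pore_intensity=120,
            noise_sd=4.0, seed=11,
        )
        image, _ = generate_weave_image(params)
        stretched = stretch_contrast(image, 1, 99)
        thr = compute_threshold(stretched, "otsu")
        labels = classify_pixels(stretched, thr).labels
        agreement = (labels == geometric_pore_truth(params)).mean()
        assert agreement >= 0.98


class TestComputeThreshold:
    def test_two_valued_image_split_exactly(self):
        img = _image(np.tile([40, 200], 128).reshape(16, 16))
        thr = compute_threshold(img, "otsu")
        assert 40 <= thr < 200
        labels = classify_pixels(img, thr).labels
        assert np.array_equal(labels, img.pixels == 200)

    def test_manual_passthrough_and_validation(self):
        img = _image(np.zeros((8, 8)))
        assert compute_threshold(img, "manual", 128) == 128.0
        with pytest.raises(ValueError):
            compute_threshold(img, "manual")
        with pytest.raises(ValueError):
            compute_threshold(img, "otsu", manual_value=10)

    def test_constant_image_has_no_otsu_threshold(self):
        with pytest.raises(NoThresholdError):
            compute_threshold(_image(np.full((16, 16), 99)), "otsu")

    def test_otsu_matches_brute_force_on_bimodal_mixture(self, rng):
        for means in [(60, 180), (90, 150), (40, 220)]:
            px = np.concatenate(
                [rng.normal(means[0], 12, 3000), rng.normal(means[1], 15, 2000)]
            ).clip(0, 255)
            img = _image(px.round().reshape(50, 100))
            thr = compute_threshold(img, "otsu")
            assert abs(thr - brute_force_otsu(img.pixels)) <= 5


class TestClassifyPixels:
    def test_all_bright_is_all_pore(self):
        mask = classify_pixels(_image(np.full((10, 10), 250)), 128)
        assert mask.n_pore == 100 and mask.n_yarn == 0

    def test_all_dark_is_all_yarn(self):
        mask = classify_pixels(_image(np.full((10, 10), 10)), 128)
        assert mask.n_yarn == 100 and mask.n_pore == 0

    @given(st.integers(0, 255), st.integers(1, 30))
    def test_partition_invariant(self, threshold, side):
        rng = np.random.default_rng(threshold * 31 + side)
        mask = classify_pixels(
            _image(rng.integers(0, 256, (side, side))), threshold
        )
        assert mask.n_pore + mask.n_yarn == mask.n_total == side * side

    def test_noiseless_weave_classified_exactly(self, quarter_gap_params):
        image, _ = generate_weave_image(quarter_gap_params)
        midpoint = (
            quarter_gap_params.yarn_intensity + quarter_gap_params.pore_intensity
        ) / 2
        labels = classify_pixels(image, midpoint).labels
        assert np.array_equal(labels, geometric_pore_truth(quarter_gap_params))

    def test_affine_intensity_invariance_with_recomputed_otsu(self, rng):
        params = WeaveParams(
            warp_pitch=60, weft_pitch=60, warp_width=30, weft_width=30,
            image_size=(512, 512), noise_sd=6.0, seed=5,
        )
        image, _ = generate_weave_image(params)
        base = classify_pixels(image, compute_threshold(image)).labels
        for gain, offset in [(0.5, 60.0), (0.8, 20.0)]:
            transformed = FabricImage(
                np.round(image.pixels * gain + offset).clip(0, 255).astype(np.uint8)
            )
            labels = classify_pixels(transformed, compute_threshold(transformed)).labels
            assert np.array_equal(labels, base)


class TestSegmentPipeline:
    def test_auto_contrast_triggers_only_on_dense_fabric(self):
        dense = WeaveParams(  # ~1% pore fraction: triggers the stretch
            warp_pitch=100, weft_pitch=100, warp_width=90, weft_width=90,
            image_size=(600, 600), yarn_intensity=100, pore_intensity=160,
            noise_sd=2.0, seed=2,
        )
        loose = WeaveParams(
            warp_pitch=100, weft_pitch=100, warp_width=50, weft_width=50,
            image_size=(600, 600), noise_sd=3.0, seed=2,
        )
        assert segment(generate_weave_image(dense)[0]).contrast_adjusted
        assert not segment(generate_weave_image(loose)[0]).contrast_adjusted

    def test_rgb_input_converted_by_luma(self):
        rgb = np.zeros((32, 32, 3), dtype=np.uint8)
        rgb[..., 1] = 200  # pure green
        img = FabricImage(rgb)
        assert img.pixels.ndim == 2
        assert int(img.pixels[0, 0]) == round(0.587 * 200)
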