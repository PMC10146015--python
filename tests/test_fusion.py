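"""fusion_core: the six-step pipeline, step by step and end to end."""

from __future__ import annotations

import numpy as np
import pytest

from bpfuse import (
    FusionConfig,
    LesionSpec,
    PhantomSpec,
    SliceTriplet,
    apply_jet,
    combined_channels,
    extract_channels,
    fuse,
    generate_phantom,
    intensity_mask,
    invert,
    resize_to,
    rgb_to_lab,
    stack_rgb,
)
from bpfuse.fusion import LabChannels

from conftest import scalar_fuse_intensity

# CIELAB references for the sRGB primaries under D65, frozen from an
# independent colorimetry computation (skimage.color.rgb2lab)
_LAB_REFERENCES = {
    (255, 0, 0): (53.2406, 80.0923, 67.2028),
    (0, 255, 0): (87.7351, -86.1830, 83.1797),
    (0, 0, 255): (32.2957, 79.1856, -107.8573),
    (255, 255, 255): (100.0, 0.0, 0.0),
    (0, 0, 0): (0.0, 0.0, 0.0),
}


class TestResize:
    def test_identity_when_already_target_size(self, rng):
        img = rng.integers(0, 256, (600, 600), dtype=np.uint8)
        assert np.array_equal(resize_to(img, FusionConfig()), img)

    @pytest.mark.parametrize("interp", ["nearest", "bilinear", "bicubic"])
    def test_constant_image_preserved(self, interp):
        img = np.full((96, 96), 77, dtype=np.uint8)
        out = resize_to(img, FusionConfig(out_size=600, interpolation=interp))
        assert out.shape == (600, 600)
        assert np.all(out == 77)

    def test_checkerboard_upsampling_preserves_mean(self):
        img = (np.indices((96, 96)).sum(axis=0) % 2 * 255).astype(np.uint8)
        out = resize_to(img, FusionConfig(out_size=600))
        assert abs(float(out.mean()) - float(img.mean())) < 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resize_to(np.zeros((0, 4), dtype=np.uint8), FusionConfig())


class TestInvert:
    def test_endpoints_and_involution(self, rng):
        assert invert(np.array([[0]], dtype=np.uint8))[0, 0] == 255
        assert invert(np.array([[255]], dtype=np.uint8))[0, 0] == 0
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        assert np.array_equal(invert(invert(img)), img)


class TestStackRGB:
    def test_channel_order_is_t2_adc_dwi(self):
        full = np.full((4, 4), 255, dtype=np.uint8)
        zero = np.zeros((4, 4), dtype=np.uint8)
        assert np.all(stack_rgb(full, full, full) == 255)
        red = stack_rgb(full, zero, zero)
        assert np.all(red[..., 0] == 255) and not red[..., 1:].any()

    def test_dimension_mismatch_names_sequence(self):
        a = np.zeros((600, 600), dtype=np.uint8)
        b = np.zeros((599, 600), dtype=np.uint8)
        with pytest.raises(ValueError, match="dwi"):
            stack_rgb(a, a, b)


class TestRgbToLab:
    @pytest.mark.parametrize("rgb,expected", list(_LAB_REFERENCES.items()))
    def test_reference_colors(self, rgb, expected):
        img = np.array([[rgb]], dtype=np.uint8)
        lab = rgb_to_lab(img)
        got = (lab.luminance[0, 0], lab.alpha[0, 0], lab.beta[0, 0])
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, abs=0.1)

    def test_whitepoint_within_centi_units(self):
        lab = rgb_to_lab(np.full((1, 1, 3), 255, dtype=np.uint8))
        assert lab.luminance[0, 0] == pytest.approx(100.0, abs=1e-2)
        assert lab.alpha[0, 0] == pytest.approx(0.0, abs=1e-2)
        assert lab.beta[0, 0] == pytest.approx(0.0, abs=1e-2)

    def test_matches_skimage_on_random_images(self, rng):
        from skimage import color

        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        ours = rgb_to_lab(img)
        ref = color.rgb2lab(img)
        # skimage derives its sRGB matrix at slightly different constant
        # precision; agreement to ~1e-2 validates the transform
        np.testing.assert_allclose(ours.luminance, ref[..., 0], atol=1e-2)
        np.testing.assert_allclose(ours.alpha, ref[..., 1], atol=1e-2)
        np.testing.assert_allclose(ours.beta, ref[..., 2], atol=1e-2)

    def test_luminance_bounded(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        lab = rgb_to_lab(img)
        assert lab.luminance.min() >= 0.0
        assert lab.luminance.max() <= 100.0 + 1e-9


class TestExtractChannels:
    @pytest.mark.parametrize("lum,expected", [(100.0, 255), (0.0, 0), (50.0, 128)])
    def test_luminance_scaling(self, lum, expected):
        lab = LabChannels(np.array([[lum]]), np.array([[1.5]]), np.array([[-2.5]]))
        lum8, alpha, beta = extract_channels(lab)
        assert lum8[0, 0] == expected  # 2.55 * 50 = 127.5 rounds up to 128
        assert alpha[0, 0] == 1.5 and beta[0, 0] == -2.5


class TestCombinedChannels:
    @pytest.mark.parametrize("a,b,expected", [(0, 0, 0), (3, 4, 5), (-80, 60, 100)])
    def test_chroma_magnitude(self, a, b, expected):
        out = combined_channels(np.array([[float(a)]]), np.array([[float(b)]]))
        assert out[0, 0] == expected

    def test_clips_at_255(self):
        out = combined_channels(np.array([[500.0]]), np.array([[0.0]]))
        assert out[0, 0] == 255


class TestIntensityMask:
    def test_subtraction_and_saturation(self):
        lum = np.array([[200, 30]], dtype=np.uint8)
        comb = np.array([[50, 90]], dtype=np.uint8)
        assert intensity_mask(lum, comb).tolist() == [[150, 0]]

    def test_gray_triplet_intensity_equals_luminance(self, rng):
        # equal R=G=B is achromatic: chroma 0, intensity == luminance8
        g = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        res = fuse(SliceTriplet(invert(g), invert(g), g), FusionConfig(out_size=16))
        assert not res.combined.any()
        assert np.array_equal(res.intensity, res.luminance8)


class TestApplyJet:
    def test_endpoints_and_midpoint(self):
        img = np.array([[0, 128, 255]], dtype=np.uint8)
        out = apply_jet(img, FusionConfig())
        np.testing.assert_allclose(out[0, 0], [0.0, 0.0, 0.5], atol=1e-9)
        np.testing.assert_allclose(out[0, 2], [0.5, 0.0, 0.0], atol=1e-9)
        assert out[0, 1, 1] >= 0.99  # cyan-yellow transition: green near max

    def test_64_entry_table_floors_index(self):
        cfg = FusionConfig(colormap_entries=64)
        img = np.array([[0, 3, 4, 255]], dtype=np.uint8)
        out = apply_jet(img, cfg)
        # values 0..3 share entry 0; value 4 moves to entry 1
        np.testing.assert_allclose(out[0, 0], out[0, 1])
        assert not np.allclose(out[0, 1], out[0, 2])
        np.testing.assert_allclose(out[0, 3], [0.5, 0.0, 0.0], atol=1e-9)


class TestFuse:
    def test_constant_triplet_gives_constant_intensity(self):
        c = np.full((32, 32), 128, dtype=np.uint8)
        res = fuse(SliceTriplet(c, c, c), FusionConfig(out_size=32))
        assert len(np.unique(res.intensity)) == 1
        assert res.intensity.shape == (32, 32)

    def test_all_intermediates_share_output_size(self, rng):
        t2, adc, dwi = (rng.integers(0, 256, (20, 20), dtype=np.uint8)
                        for _ in range(3))
        res = fuse(SliceTriplet(t2, adc, dwi), FusionConfig(out_size=64))
        for arr in (res.t2_inv, res.adc_inv, res.luminance8, res.combined,
                    res.intensity):
            assert arr.shape == (64, 64)
        assert res.rgb.shape == (64, 64, 3)
        assert res.jet_rgb.shape == (64, 64, 3)

    def test_intensity_never_exceeds_luminance(self, rng):
        t2, adc, dwi = (rng.integers(0, 256, (32, 32), dtype=np.uint8)
                        for _ in range(3))
        res = fuse(SliceTriplet(t2, adc, dwi), FusionConfig(out_size=32))
        assert np.all(res.intensity <= res.luminance8)

    def test_pr5_lesion_brighter_than_background(self, pr5_phantom_spec):
        triplet, mask = generate_phantom(pr5_phantom_spec)
        res = fuse(triplet, FusionConfig(out_size=pr5_phantom_spec.size))
        lesion_mean = res.intensity[mask == 3].mean()
        background_mean = res.intensity[mask == 0].mean()
        assert lesion_mean > background_mean

    def test_matches_scalar_oracle_bit_for_bit(self, random_triplet):
        t2, adc, dwi = random_triplet
        res = fuse(SliceTriplet(t2, adc, dwi), FusionConfig(out_size=32))
        assert np.array_equal(res.intensity, scalar_fuse_intensity(t2, adc, dwi))


def _lesion_mean(t2_level, adc_level, dwi_level, size=96):
    """Fused mean intensity of a centered disk with the given signals."""
    spec = PhantomSpec(
        size=size,
        gland_center=(size / 2, size / 2),
        gland_axes=(size * 0.4, size * 0.45),
        lesions=[LesionSpec(center=(size / 2, size / 2), radius=10,
                            pattern="pr5",
                            signal_levels=(t2_level, adc_level, dwi_level))],
        noise_sigma=0.0,
        seed=3,
    )
    triplet, mask = generate_phantom(spec)
    res = fuse(triplet, FusionConfig(out_size=size))
    return float(res.intensity[mask > 0].mean())


class TestSuspicionResponse:
    """The fused intensity must move with the PI-RADS signal pattern."""

    # 5-level ladders end at the calibrated pr5 defaults (50, 50, 205);
    # past the achromatic point (DWI == inverted T2/ADC) blue chroma
    # grows and intensity correctly falls again, so the monotone claim
    # applies to the approach toward the concordant pattern
    def test_monotone_in_dwi(self):
        means = [_lesion_mean(50, 50, dwi) for dwi in range(125, 206, 20)]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_monotone_decreasing_in_adc(self):
        means = [_lesion_mean(50, adc, 205) for adc in range(50, 131, 20)]
        assert all(b <= a for a, b in zip(means, means[1:]))

    def test_monotone_decreasing_in_t2(self):
        means = [_lesion_mean(t2, 50, 205) for t2 in range(50, 131, 20)]
        assert all(b <= a for a, b in zip(means, means[1:]))

    def test_shine_through_scores_below_true_restriction(self):
        # same bright DWI; high ADC (no true restriction) must lose
        shine = _lesion_mean(120, 230, 205)
        restricted = _lesion_mean(120, 50, 205)
        assert shine < restricted
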