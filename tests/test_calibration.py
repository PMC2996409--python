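import numpy as np
import pytest

from tmapunch import (
    ColorLevels,
    DegenerateImageError,
    InvalidResolutionError,
    ReferenceProfile,
    apply_transfer,
    derive_profile,
    estimate_color_levels,
    rescale_to_resolution,
    solve_transfer,
)
from tmapunch.calibration import CalibrationCoefficients


class TestEstimateColorLevels:
    def test_three_uniform_patches_recovered_exactly(self, three_patch_image):
        levels = estimate_color_levels(three_patch_image)
        assert (levels.b, levels.c, levels.n) == pytest.approx(
            (235.0, 175.0, 100.0), abs=1e-9
        )

    def test_noisy_patches_within_two_gray_levels(self, three_patch_image):
        rng = np.random.default_rng(1)
        noisy = np.clip(
            three_patch_image.astype(float) + rng.normal(0, 3, three_patch_image.shape),
            0,
            255,
        ).astype(np.uint8)
        levels = estimate_color_levels(noisy)
        assert abs(levels.b - 235) <= 2
        assert abs(levels.c - 175) <= 2
        assert abs(levels.n - 100) <= 2

    def test_uniform_image_is_degenerate(self):
        img = np.full((10, 10, 3), 255, dtype=np.uint8)
        with pytest.raises(DegenerateImageError):
            estimate_color_levels(img)


class TestSolveTransfer:
    def test_identity_when_observed_equals_reference(self, profile):
        levels = ColorLevels(b=profile.b_r, n=profile.n_r, c=profile.c_r)
        coeffs = solve_transfer(levels, profile)
        assert coeffs.a == pytest.approx(0.0, abs=1e-9)
        assert coeffs.b == pytest.approx(1.0, abs=1e-9)
        assert coeffs.c == pytest.approx(0.0, abs=1e-9)

    def test_exact_quadratic_through_known_points(self):
        # anchors (0,0), (1,2), (2,6) lie on y = x^2 + x
        ref = ReferenceProfile(b_r=6, n_r=0, c_r=2, p_ref=3, r_ref=1.0)
        coeffs = solve_transfer(ColorLevels(b=2.0, n=0.0, c=1.0), ref)
        assert coeffs.a == pytest.approx(1.0, abs=1e-9)
        assert coeffs.b == pytest.approx(1.0, abs=1e-9)
        assert coeffs.c == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_polynomial_interpolation(self, profile):
        observed = ColorLevels(b=200.0, n=90.0, c=160.0)
        coeffs = solve_transfer(observed, profile)
        expected = np.polyfit(
            [200.0, 90.0, 160.0],
            [profile.b_r, profile.n_r, profile.c_r],
            deg=2,
        )
        assert (coeffs.a, coeffs.b, coeffs.c) == pytest.approx(tuple(expected))
        # the transfer maps the observed anchors exactly onto the references
        for x, y in [(200, 235), (90, 100), (160, 175)]:
            assert coeffs(x) == pytest.approx(y, abs=1e-9)

    def test_level_ordering_is_enforced(self):
        with pytest.raises(ValueError):
            ColorLevels(b=200.0, n=90.0, c=200.0)


class TestApplyTransfer:
    def test_identity_coefficients_leave_image_unchanged(self, three_tone_tile):
        out = apply_transfer(three_tone_tile, CalibrationCoefficients(0.0, 1.0, 0.0))
        assert np.array_equal(out, three_tone_tile)

    @pytest.mark.parametrize(
        "coeffs,pixel,expected",
        [
            (CalibrationCoefficients(0.0, 1.0, 10.0), 250, 255),  # clamped
            (CalibrationCoefficients(1.0, 1.0, 0.0), 10, 110),
            (CalibrationCoefficients(0.0, 1.0, 0.5), 100, 101),  # half rounds up
        ],
    )
    def test_pointwise_values(self, coeffs, pixel, expected):
        img = np.full((2, 2, 3), pixel, dtype=np.uint8)
        assert apply_transfer(img, coeffs)[0, 0, 0] == expected


class TestRescaleToResolution:
    @pytest.mark.parametrize(
        "shape,r_in,expected",
        [
            ((100, 100), 0.23, (50, 50)),
            ((100, 100), 0.46, (100, 100)),
            ((101, 101), 0.23, (51, 51)),  # round half up
        ],
    )
    def test_output_dimensions(self, profile, shape, r_in, expected):
        img = np.zeros(shape + (3,), dtype=np.uint8)
        out = rescale_to_resolution(img, r_in, profile)
        assert out.shape[:2] == expected

    def test_aspect_ratio_within_one_pixel(self, profile):
        img = np.zeros((300, 451, 3), dtype=np.uint8)
        out = rescale_to_resolution(img, 0.3, profile)
        h, w = out.shape[:2]
        assert abs(w / h - 451 / 300) < 1.0 / h

    def test_invalid_resolution_rejected(self, profile):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(InvalidResolutionError):
            rescale_to_resolution(img, 0.0, profile)


class TestDeriveProfile:
    def test_same_mean_is_identity(self, profile):
        assert derive_profile(profile.p_ref, profile) == profile

    def test_proportional_rescaling(self, profile):
        derived = derive_profile(85, profile)
        assert (derived.b_r, derived.c_r, derived.n_r) == (118, 88, 50)
        assert derived.p_ref == 85
        assert derived.r_ref == profile.r_ref

    @pytest.mark.parametrize("p_new", [0, -5, 256])
    def test_out_of_range_mean_rejected(self, profile, p_new):
        with pytest.raises(ValueError):
            derive_profile(p_new, profile)


class TestCalibrationRoundTrip:
    def _calibrate(self, img, profile):
        return apply_transfer(img, solve_transfer(estimate_color_levels(img), profile))

    def test_calibrated_levels_hit_reference_anchors(self, profile):
        rng = np.random.default_rng(3)
        img = np.zeros((60, 90, 3), dtype=np.uint8)
        img[:, :30], img[:, 30:60], img[:, 60:] = 220, 150, 80
        img = np.clip(img + rng.normal(0, 2, img.shape), 0, 255).astype(np.uint8)
        out = self._calibrate(img, profile)
        levels = estimate_color_levels(out)
        assert abs(levels.b - profile.b_r) <= 2
        assert abs(levels.c - profile.c_r) <= 2
        assert abs(levels.n - profile.n_r) <= 2

    def test_calibration_is_idempotent_within_one_gray_level(
        self, three_patch_image, profile
    ):
        once = self._calibrate(three_patch_image, profile)
        twice = self._calibrate(once, profile)
        diff = np.abs(once.astype(int) - twice.astype(int))
        assert diff.max() <= 1


def test_profile_json_round_trip(profile):
    assert ReferenceProfile.from_json(profile.to_json()) == profile


def test_profile_invariants_enforced():
    with pytest.raises(ValueError):
        ReferenceProfile(b_r=100, n_r=150, c_r=120)
    with pytest.raises(ValueError):
        ReferenceProfile(p_ref=120)  # inconsistent with anchor mean 170
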