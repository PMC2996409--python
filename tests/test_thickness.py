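import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tmapunch import (
    classify_layering,
    count_bright,
    distance_ridge,
    euclidean_distance_map,
    local_thickness,
    render_thickness_image,
)
from tmapunch.thickness import DOUBLE_LAYER, SINGLE_LAYER, bright_count_cutoff

from helpers import brute_force_local_thickness, brute_force_ridge, random_mask

masks = arrays(bool, st.tuples(st.integers(3, 16), st.integers(3, 16)))


def _disk(r: float, size: int | None = None):
    size = size or (2 * int(r) + 5)
    yy, xx = np.mgrid[:size, :size].astype(float)
    c = size // 2
    return (yy - c) ** 2 + (xx - c) ** 2 < r * r


class TestDistanceMap:
    def test_isolated_pixel_is_one_away_from_background(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert euclidean_distance_map(m)[2, 2] == 1.0

    def test_solid_square_center_distance(self):
        # the image border counts as background
        d = euclidean_distance_map(np.ones((5, 5), dtype=bool))
        assert d[2, 2] == 3.0

    def test_empty_mask_all_zero(self):
        assert not euclidean_distance_map(np.zeros((4, 6), dtype=bool)).any()

    @given(masks)
    def test_lipschitz_across_neighbors_and_zero_on_background(self, m):
        d = euclidean_distance_map(m)
        assert (d[~m] == 0).all()
        assert (d[m] >= 1).all()
        assert (np.abs(np.diff(d, axis=0)) <= 1 + 1e-12).all()
        assert (np.abs(np.diff(d, axis=1)) <= 1 + 1e-12).all()


class TestDistanceRidge:
    def test_solid_disk_largest_ridge_disk_is_central(self):
        m = _disk(8)
        c = m.shape[0] // 2
        ridge = distance_ridge(euclidean_distance_map(m))
        assert ridge
        (y, x), r = max(ridge, key=lambda item: item[1])
        assert (y, x) == (c, c)
        assert r == 8.0

    def test_ridge_matches_brute_force_containment(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            m = random_mask(rng, max_side=14)
            ridge = {c for c, _ in distance_ridge(euclidean_distance_map(m))}
            assert ridge == brute_force_ridge(m)

    def test_thin_line_every_pixel_is_maximal(self):
        m = np.zeros((5, 9), dtype=bool)
        m[2, 2:7] = True
        ridge = distance_ridge(euclidean_distance_map(m))
        assert sorted(c for c, _ in ridge) == [(2, x) for x in range(2, 7)]
        assert all(r == 1.0 for _, r in ridge)

    def test_empty_mask_has_no_ridge(self):
        assert distance_ridge(np.zeros((4, 4))) == []

    @given(masks)
    def test_every_foreground_pixel_is_covered(self, m):
        ridge = distance_ridge(euclidean_distance_map(m))
        cover = np.zeros(m.shape, dtype=bool)
        for (y, x), r in ridge:
            yy, xx = np.mgrid[: m.shape[0], : m.shape[1]]
            # open disk on exact squared distances: |p-c|^2 <= r^2 - 1
            cover |= (yy - y) ** 2 + (xx - x) ** 2 <= round(r * r) - 1
        assert (cover[m]).all()
        assert not cover[~m].any()


class TestLocalThickness:
    @pytest.mark.parametrize("r", [5, 8, 11])
    def test_disk_thickness_matches_diameter(self, r):
        tau = local_thickness(_disk(r))
        assert abs(tau.max() - 2 * r) <= 1.0

    @pytest.mark.parametrize("w", [7, 10, 13])
    def test_strip_interior_thickness_matches_width(self, w):
        m = np.zeros((w + 20, 4 * w), dtype=bool)
        m[10 : 10 + w, 5 : 4 * w - 5] = True
        tau = local_thickness(m)
        assert abs(tau[10 + w // 2, 2 * w] - w) <= 1.0

    def test_matches_exhaustive_oracle_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            m = random_mask(rng)
            assert np.array_equal(local_thickness(m), brute_force_local_thickness(m))

    def test_monotone_under_mask_growth(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            m = random_mask(rng, max_side=24)
            grown = m | (rng.random(m.shape) < 0.15)
            assert (local_thickness(grown) >= local_thickness(m) - 1e-12).all()

    @given(masks)
    def test_bounds_relative_to_distance_map(self, m):
        tau = local_thickness(m)
        d = euclidean_distance_map(m)
        assert (tau[~m] == 0).all()
        assert (tau[m] >= 2 * d[m] - 2).all()
        # open-disk convention: a full n-wide mask has centre distance
        # (n+1)//2 + ..., giving tau at most one pixel above the side length
        assert tau.max() <= min(m.shape) + 1 + 1e-12


class TestRendering:
    def test_zero_thickness_renders_black(self):
        img = render_thickness_image(np.zeros((4, 4)), r_ref=0.46)
        assert not img.any()

    def test_full_scale_value_renders_white(self):
        img = render_thickness_image(np.full((2, 2), 40.0), r_ref=0.5, tau_display_max=20.0)
        assert (img == 255).all()

    def test_half_scale_rounds_half_up(self):
        img = render_thickness_image(np.full((2, 2), 20.0), r_ref=0.5, tau_display_max=20.0)
        assert (img == 128).all()


class TestBrightCount:
    def test_cutoff_is_221_for_reference_profile(self, profile):
        img = np.zeros((10, 10), dtype=np.uint8)
        assert count_bright(img, profile) == 0
        img[0, :5] = 221  # pixels exactly at 1.3 * 170 are counted
        img[1, :3] = 220
        assert count_bright(img, profile) == 5

    def test_counts_saturated_pixels(self, profile):
        img = np.zeros((20, 20), dtype=np.uint8)
        img.flat[:100] = 255
        assert count_bright(img, profile) == 100


class TestClassifyLayering:
    def test_cutoff_at_reference_resolution(self):
        assert bright_count_cutoff(0.46) == pytest.approx(2504.73, abs=0.01)
        assert classify_layering(2505, 0.46) == DOUBLE_LAYER
        assert classify_layering(2504, 0.46) == SINGLE_LAYER

    def test_zero_count_is_single_layer(self):
        assert classify_layering(0, 0.46) == SINGLE_LAYER

    def test_strictly_more_than_cutoff_required(self):
        # at r_ref = 1 the cutoff is exactly 530
        assert classify_layering(530, 1.0) == SINGLE_LAYER
        assert classify_layering(531, 1.0) == DOUBLE_LAYER


def test_double_ring_outscores_single_ring_in_bright_pixels(profile):
    """A double nuclei layer around the same lumen yields strictly more
    bright pixels than a single layer, at the default rendering scale."""
    from tmapunch import NucleiMask, clean_mask

    def ring_mask(lumen_um, wall_um):
        px = 1.0 / profile.r_ref
        size = int(2 * (lumen_um + wall_um + 4) * px)
        yy, xx = np.mgrid[:size, :size].astype(float)
        c = size / 2
        d = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        ring = (d >= lumen_um * px) & (d < (lumen_um + wall_um) * px)
        return clean_mask(NucleiMask(ring), r_ref=profile.r_ref).mask

    for lumen in (3.0, 5.0, 8.0):
        single = ring_mask(lumen, 4.5)
        double = ring_mask(lumen, 10.0)
        b_single = count_bright(
            render_thickness_image(local_thickness(single), profile.r_ref), profile
        )
        b_double = count_bright(
            render_thickness_image(local_thickness(double), profile.r_ref), profile
        )
        assert b_double > b_single
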