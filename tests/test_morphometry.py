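"""Morphometry chain: frustum arithmetic, segmentation, midline, widths."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormquant import (
    CalibratedImage,
    Midline,
    WidthProfile,
    arc_length,
    extract_midline,
    frustum_volume,
    measure_worm,
    segment_worm,
    width_at,
    width_profile,
)
from wormquant.errors import MidlineError, SegmentationError
from wormquant.synthetic import rendered_mask


def quadrature_volume(radius_fn, length_um, n=100_001):
    """Solid-of-revolution volume by dense trapezoid quadrature (oracle)."""
    s = np.linspace(0.0, 1.0, n)
    r = radius_fn(s)
    return float(np.trapezoid(np.pi * r * r, s * length_um))


def profile_from_fn(radius_fn, length_um):
    k = np.arange(31) / 30.0
    return WidthProfile(radii_um=radius_fn(k), segment_length_um=length_um / 30.0)


class TestFrustumVolume:
    def test_constant_profile_reduces_to_cylinder(self):
        profile = WidthProfile(np.full(31, 10.0), segment_length_um=10.0)
        assert frustum_volume(profile) == pytest.approx(np.pi * 100.0 * 300.0, rel=1e-12)

    def test_linear_taper_reduces_to_cone(self):
        profile = WidthProfile(np.linspace(10.0, 0.0, 31), segment_length_um=10.0)
        assert frustum_volume(profile) == pytest.approx(np.pi * 100.0 * 300.0 / 3.0, rel=1e-12)

    def test_piecewise_linear_profiles_are_exact(self, rng):
        # the frustum sum IS the solid-of-revolution integral for any
        # radius profile linear within each segment
        knots = rng.uniform(2.0, 20.0, size=31)
        profile = WidthProfile(knots, segment_length_um=7.0)
        h = 7.0
        exact = sum(
            np.pi * h / 3.0 * (knots[i] ** 2 + knots[i] * knots[i + 1] + knots[i + 1] ** 2)
            for i in range(30)
        )
        assert frustum_volume(profile) == pytest.approx(exact, rel=1e-12)

    def test_matches_quadrature_for_smooth_profiles(self, rng):
        for _ in range(10):
            a, b, c = rng.uniform(0.5, 2.0, 3)
            fn = lambda s: 10.0 + a * np.sin(np.pi * s) + b * s * (1 - s) * 4 + c * np.cos(
                2 * np.pi * s
            )  # noqa: E731
            vol = frustum_volume(profile_from_fn(fn, 900.0))
            assert vol == pytest.approx(quadrature_volume(fn, 900.0), rel=5e-3)

    @given(scale=st.floats(0.1, 10.0), h_scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_covariance(self, scale, h_scale):
        radii = np.linspace(5.0, 12.0, 31)
        base = frustum_volume(WidthProfile(radii, 10.0))
        scaled_r = frustum_volume(WidthProfile(radii * scale, 10.0))
        scaled_h = frustum_volume(WidthProfile(radii, 10.0 * h_scale))
        assert scaled_r == pytest.approx(base * scale**2, rel=1e-9)
        assert scaled_h == pytest.approx(base * h_scale, rel=1e-9)

    def test_rejects_wrong_profile_shape_or_negative_radius(self):
        with pytest.raises(ValueError):
            WidthProfile(np.full(30, 5.0), 10.0)
        with pytest.raises(ValueError):
            WidthProfile(np.concatenate([[-1.0], np.full(30, 5.0)]), 10.0)


class TestArcLength:
    def test_straight_midline_closed_form(self):
        pts = np.column_stack([np.full(501, 10.0), np.arange(501.0)])
        mid = Midline(pts, np.arange(501.0))
        assert arc_length(mid, pixels_per_um=2.0) == pytest.approx(250.0)

    def test_semicircle_closed_form(self):
        theta = np.linspace(0, np.pi, 2001)
        pts = np.column_stack([100 * np.sin(theta), 100 * np.cos(theta)]) + 200
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mid = Midline(pts, np.concatenate([[0.0], np.cumsum(seg)]))
        assert arc_length(mid, 1.0) == pytest.approx(np.pi * 100.0, rel=5e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            Midline(np.array([[0.0, 0.0]]), np.array([0.0]))


class TestSegmentation:
    def test_blank_image_raises_no_worm(self):
        blank = CalibratedImage(np.zeros((64, 64)), pixels_per_um=1.0)
        with pytest.raises(SegmentationError, match="no worm"):
            segment_worm(blank)

    def test_largest_component_retained(self):
        px = np.zeros((100, 100))
        px[40:60, 10:80] = 1000.0  # worm
        px[10:14, 10:14] = 1000.0  # debris blob below min_area
        mask = segment_worm(CalibratedImage(px, 1.0))
        assert mask[50, 40]
        assert not mask[11, 11]

    def test_border_touching_worm_rejected(self):
        px = np.zeros((64, 64))
        px[0:30, 20:45] = 1000.0  # runs off the top edge
        with pytest.raises(SegmentationError, match="clipped"):
            segment_worm(CalibratedImage(px, 1.0))

    def test_mask_area_matches_generator_oracle(self, cylinder_worm):
        spec, image, _ = cylinder_worm
        mask = segment_worm(image)
        assert mask.sum() == pytest.approx(rendered_mask(spec).sum(), rel=0.05)


class TestMidline:
    def test_straight_worm_arc_length(self, cylinder_worm):
        spec, image, truth = cylinder_worm
        midline = extract_midline(segment_worm(image))
        assert midline.length_px == pytest.approx(truth.length_um * spec.pixels_per_um, rel=0.01)

    def test_endpoint_ordering_deterministic(self, cylinder_worm):
        _, image, _ = cylinder_worm
        mask = segment_worm(image)
        midline = extract_midline(mask)
        first, last = tuple(midline.points[0]), tuple(midline.points[-1])
        assert first < last

    def test_ring_topology_rejected(self):
        yy, xx = np.mgrid[:101, :101]
        ring = (np.hypot(yy - 50, xx - 50) < 40) & (np.hypot(yy - 50, xx - 50) > 25)
        with pytest.raises(MidlineError, match="ring"):
            extract_midline(ring)

    def test_rotation_leaves_arc_length_invariant(self, small_worm):
        _, image, _ = small_worm
        mask = segment_worm(image)
        len_a = extract_midline(mask).length_px
        len_b = extract_midline(np.rot90(mask).copy()).length_px
        assert len_b == pytest.approx(len_a, rel=5e-3)


class TestWidths:
    def test_mid_width_of_constant_radius_worm(self, cylinder_worm):
        spec, image, truth = cylinder_worm
        mask = segment_worm(image)
        midline = extract_midline(mask)
        w = width_at(midline, mask, 0.5, spec.pixels_per_um)
        # within one pixel equivalent of the true diameter
        assert abs(w - truth.mid_width_um) <= 1.0 / spec.pixels_per_um

    def test_arc_position_outside_unit_interval_rejected(self, cylinder_worm):
        spec, image, _ = cylinder_worm
        mask = segment_worm(image)
        midline = extract_midline(mask)
        with pytest.raises(ValueError):
            width_at(midline, mask, 1.2, spec.pixels_per_um)

    def test_profile_has_31_entries_and_constant_interior(self, cylinder_worm):
        spec, image, truth = cylinder_worm
        mask = segment_worm(image)
        midline = extract_midline(mask)
        profile = width_profile(midline, mask, spec.pixels_per_um)
        assert profile.radii_um.shape == (31,)
        interior = profile.radii_um[1:30]
        assert np.allclose(interior, truth.mid_width_um / 2, rtol=0.02)

    def test_tapered_worm_tip_radii_near_zero(self, tapered_worm):
        spec, image, truth = tapered_worm
        mask = segment_worm(image)
        midline = extract_midline(mask)
        profile = width_profile(midline, mask, spec.pixels_per_um)
        assert profile.radii_um[0] < 0.15 * truth.mid_width_um / 2
        assert profile.radii_um[30] < 0.15 * truth.mid_width_um / 2


class TestMeasureWorm:
    def test_cylinder_fixture_recovery(self, cylinder_worm):
        _, image, truth = cylinder_worm
        m = measure_worm(image)
        assert m.length_um == pytest.approx(truth.length_um, rel=0.01)
        assert m.mid_width_um == pytest.approx(truth.mid_width_um, rel=0.04)
        assert m.volume_um3 == pytest.approx(truth.volume_um3, rel=0.05)

    def test_constant_radius_recovery_tight(self, cylinder_worm):
        # joint generator/estimator contract at calibration >= 5 px/µm
        _, image, truth = cylinder_worm
        m = measure_worm(image)
        assert m.length_um == pytest.approx(truth.length_um, rel=0.01)
        assert m.volume_um3 == pytest.approx(truth.volume_um3, rel=0.02)

    def test_measurement_is_deterministic(self, small_worm):
        _, image, _ = small_worm
        a = measure_worm(image)
        b = measure_worm(image)
        assert (a.length_um, a.mid_width_um, a.volume_um3) == (
            b.length_um,
            b.mid_width_um,
            b.volume_um3,
        )

    def test_translation_invariance(self, small_worm):
        _, image, _ = small_worm
        base = measure_worm(image)
        shifted = np.roll(np.roll(image.pixels, 7, axis=0), -5, axis=1)
        m = measure_worm(CalibratedImage(shifted, image.pixels_per_um))
        assert m.length_um == pytest.approx(base.length_um, rel=0.01)
        assert m.volume_um3 == pytest.approx(base.volume_um3, rel=0.01)

    def test_rotation_invariance(self, small_worm):
        _, image, _ = small_worm
        base = measure_worm(image)
        m = measure_worm(CalibratedImage(np.rot90(image.pixels).copy(), image.pixels_per_um))
        assert m.length_um == pytest.approx(base.length_um, rel=0.01)
        assert m.mid_width_um == pytest.approx(base.mid_width_um, rel=0.01)
        assert m.volume_um3 == pytest.approx(base.volume_um3, rel=0.01)
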