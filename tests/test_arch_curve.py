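"""Dental arch curve creation: clustering, quadrangle, parabola, spline."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbctpano import Image2D, mip_axial
from cbctpano.arch_curve import (ArchExtractionError, build_hermite_spline,
                                 fit_parabola, isolate_arch,
                                 sample_perpendicular_lines,
                                 segment_bone, select_control_points,
                                 spatial_quadrangle)
from cbctpano.phantom import jaw_footprints


def as_image(data):
    return Image2D(data=np.asarray(data, dtype=float), spacing=np.ones(2))


class TestSegmentBone:
    def test_two_separable_intensities(self, rng):
        data = np.zeros((30, 30))
        bright = rng.choice(900, size=90, replace=False)
        data.flat[bright] = 100.0
        mask, thr = segment_bone(as_image(data), k=2, seed=0, top_clusters=1)
        assert 0.0 < thr.threshold < 100.0
        np.testing.assert_array_equal(mask, data == 100.0)

    def test_fixed_seed_is_deterministic(self, rng):
        data = rng.normal(size=(40, 40)) * 100
        m1, _ = segment_bone(as_image(data), k=5, seed=3)
        m2, _ = segment_bone(as_image(data), k=5, seed=3)
        np.testing.assert_array_equal(m1, m2)

    def test_k_reduced_when_fewer_distinct_values(self):
        data = np.zeros((10, 10))
        data[5:, :] = 7.0
        with pytest.warns(UserWarning, match="reducing k"):
            mask, thr = segment_bone(as_image(data), k=5, seed=0)
        assert thr.k == 2
        assert mask.sum() == 50

    def test_phantom_mip_mask_covers_all_enamel(self, default_phantom):
        vol, truth = default_phantom
        mip = mip_axial(vol)
        mask, _ = segment_bone(mip, k=5, seed=0)
        enamel = mip.data == truth.config.enamel
        assert np.all(mask[enamel])

    def test_centers_sorted_and_threshold_between(self, rng):
        data = rng.normal(size=(40, 40)) * 100
        _, thr = segment_bone(as_image(data), k=4, seed=0)
        centers = np.asarray(thr.cluster_centers)
        assert np.all(np.diff(centers) > 0)
        assert centers[-2] < thr.threshold < centers[-1]


class TestSpatialQuadrangle:
    def test_filled_rectangle_covers_p_tightly(self):
        mask = np.zeros((60, 80), dtype=bool)
        mask[10:50, 20:70] = True
        q = spatial_quadrangle(mask, p=0.75)
        assert 0.75 <= q.covered_fraction <= 0.80
        np.testing.assert_allclose(q.center, [29.5, 44.5])

    def test_matches_exhaustive_growth_oracle(self, rng):
        mask = rng.random((40, 40)) > 0.6
        q = spatial_quadrangle(mask, p=0.75)
        pts = np.argwhere(mask).astype(float)
        center, std = pts.mean(0), np.maximum(pts.std(0), 0.5)
        # brute force: grow t on a fine grid, first box covering >= p
        for t in np.linspace(0, 4, 8001):
            cov = np.mean(np.all(np.abs(pts - center) <= t * std + 1e-12, axis=1))
            if cov >= 0.75:
                break
        assert q.covered_fraction == pytest.approx(cov, abs=1e-9)

    def test_p_near_one_reaches_mask_extent(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[5:45, 10:40] = True
        q = spatial_quadrangle(mask, p=0.999)
        pts = np.argwhere(mask)
        assert q.contains(pts).mean() >= 0.999

    def test_phantom_quadrangle_excludes_jaw_wings(self, default_phantom):
        vol, truth = default_phantom
        mip = mip_axial(vol)
        mask, _ = segment_bone(mip, k=5, seed=0)
        q = spatial_quadrangle(mask, p=0.75)
        _, wings = jaw_footprints(truth.config)
        wing_px = np.argwhere(wings & mask)
        assert len(wing_px) > 0
        assert q.contains(wing_px).mean() <= 0.10

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10**6), st.floats(0.2, 0.95))
    def test_covered_fraction_at_least_p(self, seed, p):
        rng = np.random.default_rng(seed)
        mask = rng.random((25, 25)) > 0.5
        if not mask.any():
            mask[3, 4] = True
        q = spatial_quadrangle(mask, p=p)
        assert q.covered_fraction >= p - 1e-12


class TestIsolateArch:
    def test_covering_quadrangle_is_identity(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:20, 5:25] = True
        q = spatial_quadrangle(mask, p=0.999)
        np.testing.assert_array_equal(isolate_arch(mask, q), mask)

    def test_disjoint_quadrangle_errors(self):
        from cbctpano.arch_curve import Quadrangle

        mask = np.zeros((30, 30), dtype=bool)
        mask[25:, 25:] = True
        q = Quadrangle(center=(2.0, 2.0), half_extents=(1.0, 1.0), covered_fraction=0.0)
        with pytest.raises(ArchExtractionError, match="no dental arch"):
            isolate_arch(mask, q)


class TestFitParabola:
    def test_exact_recovery_on_noiseless_points(self):
        # pixels exactly on y = 0.01 x^2 - 2x + 110
        mask = np.zeros((200, 200), dtype=bool)
        xs = np.arange(40, 161)
        ys = 0.01 * xs**2 - 2 * xs + 110
        keep = (ys >= 0) & (ys < 200) & (np.abs(ys - np.round(ys)) < 1e-9)
        mask[xs[keep], np.round(ys[keep]).astype(int)] = True
        assert mask.sum() >= 10
        pb = fit_parabola(mask)
        x_apex_true = 100.0
        y_apex_true = 0.01 * x_apex_true**2 - 2 * x_apex_true + 110
        np.testing.assert_allclose(pb.apex(), [x_apex_true, y_apex_true], atol=1e-6)

    def test_collinear_pixels_rejected(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:40, 25] = True
        with pytest.raises(ArchExtractionError, match="collinear|degenerate"):
            fit_parabola(mask)

    def test_phantom_apex_recovered_within_3px(self, default_phantom):
        vol, truth = default_phantom
        mip = mip_axial(vol)
        mask, _ = segment_bone(mip, k=5, seed=0)
        q = spatial_quadrangle(mask, p=0.75)
        pb = fit_parabola(isolate_arch(mask, q))
        a, b, c = truth.arch_coeffs
        x_true = -b / (2 * a)
        true_apex = np.array([x_true, a * x_true**2 + b * x_true + c])
        assert np.linalg.norm(pb.apex() - true_apex) < 3.0


class TestControlPoints:
    @staticmethod
    def _parabola_mask():
        mask = np.zeros((160, 160), dtype=bool)
        xs = np.arange(30, 131)
        ys = np.round(0.028 * (xs - 80.0) ** 2 + 40).astype(int)
        mask[xs, ys] = True
        return mask

    def test_three_points_symmetric_about_apex(self):
        mask = self._parabola_mask()
        pb = fit_parabola(mask)
        ctrl = select_control_points(pb, mask, n=3)
        apex = pb.apex()
        np.testing.assert_allclose(ctrl[1], apex, atol=0.2)
        d0 = np.linalg.norm(ctrl[0] - apex)
        d2 = np.linalg.norm(ctrl[2] - apex)
        assert d0 == pytest.approx(d2, rel=1e-6)

    def test_seven_points_have_equal_arc_gaps(self):
        mask = self._parabola_mask()
        pb = fit_parabola(mask)
        ctrl = select_control_points(pb, mask, n=7)
        rot = pb.to_rotated(ctrl)
        from cbctpano.arch_curve import _parabola_arclength_rot

        x_apex = pb.apex_rot[0]
        arcs = np.asarray([float(_parabola_arclength_rot(pb, x_apex, x)) for x in rot[:, 0]])
        gaps = np.diff(np.sort(arcs))
        assert np.ptp(gaps) < 1e-6 * np.abs(gaps).mean() + 1e-6

    def test_points_lie_on_parabola(self):
        mask = self._parabola_mask()
        pb = fit_parabola(mask)
        ctrl = select_control_points(pb, mask, n=7)
        rot = pb.to_rotated(ctrl)
        np.testing.assert_allclose(rot[:, 1], pb.y_rot(rot[:, 0]), atol=1e-9)

    def test_even_n_rejected(self):
        mask = self._parabola_mask()
        pb = fit_parabola(mask)
        with pytest.raises(ValueError):
            select_control_points(pb, mask, n=6)


class TestHermiteSpline:
    def test_interpolates_control_points(self, rng):
        ctrl = rng.normal(size=(6, 2)) * 20
        curve = build_hermite_spline(ctrl)
        np.testing.assert_allclose(curve.evaluate(np.arange(6.0)), ctrl, atol=1e-12)

    def test_collinear_points_give_straight_segment(self):
        ctrl = np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 3.0]])
        curve = build_hermite_spline(ctrl)
        assert curve.total_length == pytest.approx(np.sqrt(2) * 3, rel=1e-4)

    def test_arc_length_at_least_chord(self, rng):
        ctrl = np.sort(rng.normal(size=(5,)))[:, None] * 10
        ctrl = np.column_stack([ctrl[:, 0], rng.normal(size=5) * 5])
        curve = build_hermite_spline(ctrl)
        assert curve.total_length >= np.linalg.norm(ctrl[-1] - ctrl[0]) - 1e-9

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_hermite_spline(np.array([[0, 0], [0, 0], [1, 1.0]]))

    def test_c1_at_interior_knots(self, rng):
        ctrl = np.cumsum(rng.random((7, 2)) + 0.2, axis=0)
        curve = build_hermite_spline(ctrl)
        eps = 1e-7
        for k in range(1, 6):
            left = (curve.evaluate(k) - curve.evaluate(k - eps)) / eps
            right = (curve.evaluate(k + eps) - curve.evaluate(k)) / eps
            np.testing.assert_allclose(left, right, atol=1e-4)

    def test_arclength_table_strictly_increasing(self, rng):
        ctrl = np.cumsum(rng.random((5, 2)) + 0.2, axis=0)
        curve = build_hermite_spline(ctrl)
        assert np.all(np.diff(curve.arclength_table) > 0)


class TestPerpendicularLines:
    def test_straight_curve_normals_perpendicular_and_parallel(self):
        ctrl = np.column_stack([np.linspace(0, 40, 5), np.zeros(5)])
        curve = build_hermite_spline(ctrl)
        lines = sample_perpendicular_lines(curve, step_px=5.0, half_length_px=10.0)
        dirs = np.asarray([ln.direction for ln in lines])
        assert np.abs(dirs @ np.array([1.0, 0.0])).max() < 1e-9
        assert np.abs(np.abs(dirs @ np.array([0.0, 1.0])) - 1).max() < 1e-9

    def test_step_tenth_of_length_gives_eleven_lines(self):
        ctrl = np.column_stack([np.linspace(0, 50, 5), np.zeros(5)])
        curve = build_hermite_spline(ctrl)
        lines = sample_perpendicular_lines(curve, curve.total_length / 10, 5.0)
        assert len(lines) == 11
        arcs = [ln.arc_position for ln in lines]
        np.testing.assert_allclose(arcs, np.linspace(0, curve.total_length, 11), atol=1e-6)

    def test_normals_of_circular_arch_pass_through_center(self):
        theta = np.linspace(0.2, np.pi - 0.2, 33)
        ctrl = np.column_stack([50 + 30 * np.cos(theta), 50 + 30 * np.sin(theta)])
        curve = build_hermite_spline(ctrl)
        lines = sample_perpendicular_lines(curve, step_px=4.0, half_length_px=10.0)
        for ln in lines:
            foot, d = ln.foot_xy, ln.dir_xy
            # distance from the circle center to the normal line
            v = np.array([50.0, 50.0]) - foot
            dist = abs(v[0] * d[1] - v[1] * d[0])
            assert dist < 2.0

    def test_step_exceeding_length_warns_single_line(self):
        ctrl = np.column_stack([np.linspace(0, 10, 3), np.zeros(3)])
        curve = build_hermite_spline(ctrl)
        with pytest.warns(UserWarning, match="single"):
            lines = sample_perpendicular_lines(curve, step_px=100.0, half_length_px=5.0)
        assert len(lines) == 1
        assert lines[0].arc_position == pytest.approx(curve.total_length / 2)

    def test_orientation_points_outward(self, default_result):
        res = default_result
        centroid = res.curve.interior_centroid()
        for ln in res.lines:
            assert np.dot(ln.dir_xy, ln.foot_xy - centroid) > -1e-6
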