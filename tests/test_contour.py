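"""Contour container, basic measurements, curvature, mask extraction."""

import numpy as np
import pytest

from leafmorph.contour import (
    Contour,
    curvature_profile,
    extract_contour,
    polygon_area,
    polygon_perimeter,
    resample_contour,
    smooth_contour,
)
from leafmorph.synthetic import LeafParams, generate_leaf, rasterize

from conftest import random_simple_polygon


def fan_triangulation_area(v: np.ndarray) -> float:
    """Independent area oracle: sum of signed fan-triangle areas."""
    total = 0.0
    for i in range(1, len(v) - 1):
        a, b, c = v[0], v[i], v[i + 1]
        total += 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
    return abs(total)


class TestContourContainer:
    def test_orientation_normalized_to_ccw(self):
        cw = Contour(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]]))
        assert polygon_area(cw) == pytest.approx(1.0)
        # shoelace of the stored vertices must be positive
        v = cw.vertices
        s = 0.5 * np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        assert s > 0

    def test_repeated_endpoint_dropped(self):
        c = Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 0.0]]))
        assert c.n == 3

    @pytest.mark.parametrize(
        "verts",
        [
            np.zeros((2, 2)),
            np.array([[0, 0], [1, 1], [2, 2]], float),  # collinear: zero area
        ],
    )
    def test_degenerate_rejected(self, verts):
        with pytest.raises(ValueError):
            Contour(verts)


class TestAreaPerimeter:
    def test_unit_square(self, unit_square):
        assert polygon_area(unit_square) == pytest.approx(1.0)
        assert polygon_perimeter(unit_square) == pytest.approx(4.0)

    def test_regular_4096gon_approximates_circle(self):
        th = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        c = Contour(np.column_stack([np.cos(th), np.sin(th)]))
        assert polygon_area(c) == pytest.approx(np.pi, rel=1e-4)
        assert polygon_perimeter(c) == pytest.approx(2 * np.pi, rel=1e-4)

    def test_area_matches_fan_triangulation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            c = random_simple_polygon(rng, n=int(rng.integers(5, 30)))
            assert polygon_area(c) == pytest.approx(
                fan_triangulation_area(c.vertices), rel=1e-9
            )

    def test_rigid_motion_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(3)
        c = random_simple_polygon(rng, 20)
        a0, p0 = polygon_area(c), polygon_perimeter(c)
        for _ in range(5):
            ang = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            shift = rng.uniform(-10, 10, 2)
            moved = Contour(c.vertices @ rot.T + shift)
            assert polygon_area(moved) == pytest.approx(a0, rel=1e-9)
            assert polygon_perimeter(moved) == pytest.approx(p0, rel=1e-9)
        s = 3.7
        scaled = Contour(c.vertices * s)
        assert polygon_area(scaled) == pytest.approx(a0 * s**2, rel=1e-9)
        assert polygon_perimeter(scaled) == pytest.approx(p0 * s, rel=1e-9)


class TestResample:
    def test_square_to_400_preserves_perimeter(self, unit_square):
        r = resample_contour(unit_square, 400)
        assert polygon_perimeter(r) == pytest.approx(4.0, rel=1e-3)
        assert r.n == 400

    def test_too_few_points_rejected(self, unit_square):
        with pytest.raises(ValueError):
            resample_contour(unit_square, 15)

    def test_idempotent_at_fixed_n(self, default_leaf):
        c, _ = default_leaf
        r1 = resample_contour(c, 512)
        r2 = resample_contour(r1, 512)
        step = polygon_perimeter(r1) / 512
        assert np.max(np.hypot(*(r1.vertices - r2.vertices).T)) <= step

    def test_area_stable_on_generated_leaf(self, default_leaf):
        c, truth = default_leaf
        r = resample_contour(c, 1024)
        assert polygon_area(r) == pytest.approx(truth.true_area, rel=5e-3)


class TestSmooth:
    def test_sigma_zero_is_identity(self, default_leaf):
        c, _ = default_leaf
        s = smooth_contour(c, 0.0)
        assert np.array_equal(s.vertices, c.vertices)

    def test_negative_sigma_rejected(self, unit_square):
        with pytest.raises(ValueError):
            smooth_contour(unit_square, -1.0)

    def test_circle_stays_circle(self, circle_contour):
        s = smooth_contour(circle_contour, 0.1)
        r = np.hypot(*(s.vertices - s.vertices.mean(axis=0)).T)
        assert np.ptp(r) / r.mean() < 1e-6
        assert r.mean() < 2.0  # slightly shrunk

    def test_smoothed_area_below_convex_hull_area(self, default_leaf):
        from scipy.spatial import ConvexHull

        c, _ = default_leaf
        s = smooth_contour(c, 20.0)
        hull = ConvexHull(c.vertices)
        assert polygon_area(s) <= hull.volume  # 2-D: volume is the area


class TestCurvature:
    def test_circle_kappa_is_inverse_radius(self, circle_contour):
        prof = curvature_profile(circle_contour)
        assert np.allclose(prof.kappa, 0.5, rtol=0.01)

    def test_straight_edges_of_rounded_square_are_flat(self):
        # rounded square: straight edges + quarter-circle corners
        r, side, m = 0.2, 2.0, 64
        pieces = []
        seg = np.linspace(-side / 2 + r, side / 2 - r, m)
        quarter = np.linspace(0, np.pi / 2, m)
        cx = side / 2 - r
        pieces.append(np.column_stack([seg, np.full(m, -side / 2)]))
        pieces.append(np.column_stack([cx + r * np.cos(quarter - np.pi / 2),
                                       -cx + r * np.sin(quarter - np.pi / 2)]))
        pieces.append(np.column_stack([np.full(m, side / 2), seg]))
        pieces.append(np.column_stack([cx + r * np.cos(quarter),
                                       cx + r * np.sin(quarter)]))
        pieces.append(np.column_stack([-seg, np.full(m, side / 2)]))
        pieces.append(np.column_stack([-cx + r * np.cos(quarter + np.pi / 2),
                                       cx + r * np.sin(quarter + np.pi / 2)]))
        pieces.append(np.column_stack([np.full(m, -side / 2), -seg]))
        pieces.append(np.column_stack([-cx + r * np.cos(quarter + np.pi),
                                       -cx + r * np.sin(quarter + np.pi)]))
        c = resample_contour(Contour(np.vstack(pieces)), 1024)
        prof = curvature_profile(c, smooth_sigma=0.02)
        corner_k = prof.kappa.max()
        # sample flat-edge vertices: points with |x| and |y| both < cx - r
        v = c.vertices
        flat = (np.abs(np.abs(v).max(axis=1) - side / 2) < 1e-3) & (
            np.abs(v).min(axis=1) < cx - r
        )
        assert flat.sum() > 50
        assert np.abs(prof.kappa[flat]).max() < 1e-3 * corner_k

    def test_turning_number_identity(self, default_leaf):
        c, _ = default_leaf
        rc = resample_contour(c, 2048)
        prof = curvature_profile(rc)
        ds = polygon_perimeter(rc) / 2048
        assert prof.kappa.sum() * ds == pytest.approx(2 * np.pi, rel=0.01)

    def test_nonuniform_spacing_rejected(self):
        v = np.array([[0, 0], [5, 0], [5.2, 0.1], [5, 5], [0, 5]], float)
        with pytest.raises(ValueError, match="resample"):
            curvature_profile(Contour(v))

    def test_scale_equivariance(self, default_leaf):
        c, _ = default_leaf
        rc = resample_contour(c, 1024)
        k1 = curvature_profile(rc).kappa
        k3 = curvature_profile(Contour(rc.vertices * 3.0)).kappa
        assert np.allclose(k1, 3.0 * k3, rtol=1e-9, atol=1e-12)


class TestExtractContour:
    def test_square_mask_roundtrip(self):
        sq = Contour(1000.0 * np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        mask = rasterize(sq, 5.0)
        c = extract_contour(mask, 5.0)
        assert polygon_area(c) == pytest.approx(1e6, rel=0.01)
        assert polygon_perimeter(c) == pytest.approx(4000.0, rel=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="0"):
            extract_contour(np.zeros((10, 10), bool), 1.0)

    def test_two_blobs_rejected(self):
        m = np.zeros((20, 20), bool)
        m[2:6, 2:6] = True
        m[12:16, 12:16] = True
        with pytest.raises(ValueError, match="2"):
            extract_contour(m, 1.0)

    def test_border_touching_rejected(self):
        m = np.zeros((10, 10), bool)
        m[0:5, 3:6] = True
        with pytest.raises(ValueError, match="border"):
            extract_contour(m, 1.0)

    def test_holes_are_filled(self):
        m = np.zeros((30, 30), bool)
        m[5:25, 5:25] = True
        m[12:18, 12:18] = False
        c = extract_contour(m, 1.0)
        assert polygon_area(c) == pytest.approx(400.0, rel=0.05)

    def test_leaf_roundtrip_consistency(self, default_leaf):
        c, truth = default_leaf
        pix = 1000.0 / 200.0  # blade_length / 200
        mask = rasterize(c, pix)
        e = extract_contour(mask, pix)
        assert polygon_area(e) == pytest.approx(truth.true_area, rel=0.02)
        assert polygon_perimeter(e) == pytest.approx(truth.true_perimeter, rel=0.02)
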