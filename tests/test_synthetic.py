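"""Synthetic leaf / image generator: ground-truth self-consistency."""

import numpy as np
import pytest

from leafmorph.contour import Contour, polygon_area
from leafmorph.synthetic import (
    FlatBackground,
    LeafParams,
    NucleusSpec,
    PlaneBackground,
    ZoneSpec,
    generate_cohort,
    generate_fluor_image,
    generate_leaf,
    random_nuclei,
    rasterize,
)


def shoelace(v: np.ndarray) -> float:
    return 0.5 * abs(
        np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
    )


class TestGenerateLeaf:
    def test_no_teeth_outline_convex_apart_from_petiole(self, smooth_leaf):
        c, truth = smooth_leaf
        assert truth.tooth_apices.shape == (0, 2)
        assert len(truth.true_tooth_heights) == 0
        # turning angles non-negative except near the two junction corners
        v = c.vertices
        e_prev = v - np.roll(v, 1, axis=0)
        e_next = np.roll(v, -1, axis=0) - v
        cross = e_prev[:, 0] * e_next[:, 1] - e_prev[:, 1] * e_next[:, 0]
        n = len(v)
        excl = np.zeros(n, bool)
        for j in truth.base_indices:
            lo = (np.arange(n) - j) % n
            excl |= (lo < 8) | (lo > n - 8)
        assert np.all(cross[~excl] > -1e-9)

    def test_fully_convex_without_petiole(self, convex_leaf):
        c, _ = convex_leaf
        from scipy.spatial import ConvexHull

        hull = ConvexHull(c.vertices)
        assert polygon_area(c) == pytest.approx(hull.volume, rel=1e-6)

    def test_five_teeth_give_ten_apices(self):
        _, truth = generate_leaf(LeafParams(n_teeth=5, seed=1))
        assert len(truth.tooth_apices) == 10
        assert len(truth.true_tooth_heights) == 10
        assert all(h > 0 for h in truth.true_tooth_heights)

    def test_truth_area_matches_shoelace_oracle(self):
        for seed in (0, 1, 2):
            c, truth = generate_leaf(LeafParams(n_teeth=4, noise_amp=3.0, seed=seed))
            assert truth.true_area == pytest.approx(shoelace(truth.polygon.vertices), rel=1e-9)

    def test_truth_perimeter_matches_segment_sum_oracle(self, default_leaf):
        _, truth = default_leaf
        v = truth.polygon.vertices
        seg = np.hypot(*(np.roll(v, -1, axis=0) - v).T).sum()
        assert truth.true_perimeter == pytest.approx(seg, rel=1e-9)

    def test_truth_heights_match_apex_chord_oracle(self, default_leaf):
        _, truth = default_leaf
        v = truth.polygon.vertices
        for tr, h in zip(truth.teeth, truth.true_tooth_heights):
            a = v[tr.apex_index]
            p = v[tr.sinus_prox_index]
            d = v[tr.sinus_dist_index]
            chord = d - p
            expect = abs(chord[0] * (a - p)[1] - chord[1] * (a - p)[0]) / np.hypot(*chord)
            assert h == pytest.approx(expect, rel=1e-9)

    def test_bit_for_bit_determinism(self):
        p = LeafParams(n_teeth=3, noise_amp=4.0, seed=123)
        c1, t1 = generate_leaf(p)
        c2, t2 = generate_leaf(p)
        assert np.array_equal(c1.vertices, c2.vertices)
        assert np.array_equal(t1.true_tooth_heights, t2.true_tooth_heights)

    def test_blade_length_exact_without_noise(self):
        for bl in (300.0, 1000.0, 4000.0):
            p = LeafParams(blade_length=bl, blade_width=0.34 * bl,
                           petiole_length=0.25 * bl, petiole_width=0.06 * bl)
            _, truth = generate_leaf(p)
            assert truth.true_blade_length == pytest.approx(bl, rel=2e-3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"blade_length": -1.0},
            {"tooth_height_frac": 1.2},
            {"tooth_height_frac": -0.1},
            {"n_teeth": -1},
            {"noise_amp": -2.0},
            {"tooth_width_frac": 0.8},
            {"petiole_width": 400.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_leaf(LeafParams(**kwargs))

    def test_self_intersecting_outline_rejected(self):
        # boundary noise larger than the petiole radius folds the outline
        with pytest.raises(ValueError, match="self-intersect"):
            generate_leaf(LeafParams(noise_amp=50.0, seed=3))


class TestRasterize:
    def test_unit_square_area(self):
        sq = Contour(1000.0 * np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        m = rasterize(sq, 10.0)
        assert m.sum() * 10.0**2 == pytest.approx(1e6, rel=0.01)
        # padded by at least 2 background pixels on all sides
        assert not m[:2].any() and not m[-2:].any()
        assert not m[:, :2].any() and not m[:, -2:].any()

    def test_pixel_larger_than_bbox_rejected(self, unit_square):
        with pytest.raises(ValueError, match="bounding box"):
            rasterize(unit_square, 5.0)

    def test_halving_pixel_size_reduces_area_error(self):
        th = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        disk = Contour(np.column_stack([500 * np.cos(th), 500 * np.sin(th)]))
        true = polygon_area(disk)
        err = []
        for pix in (20.0, 10.0):
            m = rasterize(disk, pix)
            err.append(abs(m.sum() * pix**2 - true))
        assert err[1] < err[0]


class TestGenerateCohort:
    def test_scaled_cohort_has_strictly_smaller_teeth(self):
        base = LeafParams(noise_amp=2.0)
        a = generate_cohort(base, 8, (400, 1200), 1.0, seed=5)
        b = generate_cohort(base, 8, (400, 1200), 0.5, seed=5)
        for (_, ta, ma), (_, tb, mb) in zip(a, b):
            assert ma["blade_length"] == pytest.approx(mb["blade_length"], rel=0.02)
            assert np.all(tb.true_tooth_heights < ta.true_tooth_heights)

    def test_zero_leaves_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(LeafParams(), 0, (200, 800))

    def test_decreasing_blade_range_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(LeafParams(), 5, (800, 200))

    def test_blade_lengths_within_range(self):
        coh = generate_cohort(LeafParams(noise_amp=0.0), 50, (200, 5000), 1.0, seed=9)
        bls = np.array([t.true_blade_length for _, t, _ in coh])
        assert np.all((bls >= 200) & (bls <= 5000))

    def test_metadata_records_genotype_and_length(self):
        coh = generate_cohort(LeafParams(), 3, (500, 700), 1.0, seed=2, genotype="mur1")
        for _, truth, meta in coh:
            assert meta["genotype"] == "mur1"
            assert meta["blade_length"] == pytest.approx(truth.true_blade_length)


class TestGenerateFluor:
    def test_zero_amplitude_zone_equals_background(self):
        z = ZoneSpec((64, 64), 10, 0.0)
        img, truth = generate_fluor_image((128, 128), FlatBackground(120.0), zone=z)
        assert np.array_equal(img, truth.background_field)
        assert truth.zone_total_signal == 0.0

    def test_disk_zone_total_is_amplitude_times_area(self):
        z = ZoneSpec((64, 64), 12, 37.0)
        img, truth = generate_fluor_image((128, 128), FlatBackground(100.0), zone=z)
        s = truth.zone_mask.sum()
        assert truth.zone_total_signal == pytest.approx(37.0 * s)
        assert (img - truth.background_field)[truth.zone_mask].sum() == pytest.approx(
            truth.zone_total_signal
        )

    def test_zone_mask_single_connected_component(self):
        from skimage.measure import label

        z = ZoneSpec((60, 60), 15, 10.0)
        _, truth = generate_fluor_image((128, 128), FlatBackground(0.0), zone=z)
        assert label(truth.zone_mask).max() == 1

    def test_truth_nuclei_intensities_sorted_match_specified(self):
        rng = np.random.default_rng(11)
        peaks = rng.permutation(np.arange(1, 21) * 15.0)
        nucs = random_nuclei((256, 256), 20, rng, peaks=peaks, min_separation=16)
        _, truth = generate_fluor_image((256, 256), FlatBackground(10.0), nuclei=nucs)
        got = sorted((m for _, m in truth.nuclei), reverse=True)
        # flat background + equal sigma: disk means order like the peaks
        order_expected = sorted(peaks, reverse=True)
        assert np.all(np.diff(got) <= 0)
        spearman = np.corrcoef(np.argsort(np.argsort(peaks)),
                               np.argsort(np.argsort([m for _, m in truth.nuclei])))[0, 1]
        assert spearman == pytest.approx(1.0)

    def test_zone_outside_image_rejected(self):
        with pytest.raises(ValueError, match="zone"):
            generate_fluor_image((64, 64), FlatBackground(0.0), zone=ZoneSpec((5, 32), 10, 1.0))

    def test_nucleus_outside_image_rejected(self):
        with pytest.raises(ValueError, match="nucleus"):
            generate_fluor_image(
                (64, 64), FlatBackground(0.0), nuclei=[NucleusSpec((70, 10), 5.0)]
            )

    def test_noise_determinism(self):
        z = ZoneSpec((64, 64), 10, 20.0)
        img1, _ = generate_fluor_image((128, 128), PlaneBackground(50, 0.1, 0.0), zone=z,
                                       noise_sigma=3.0, seed=7)
        img2, _ = generate_fluor_image((128, 128), PlaneBackground(50, 0.1, 0.0), zone=z,
                                       noise_sigma=3.0, seed=7)
        assert np.array_equal(img1, img2)
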