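"""Trauma image pipeline: projection, segmentation, metrics, ROI proposal."""

import numpy as np
import pytest

from retroprobe import trauma as T
from retroprobe import synthetic as syn


def _disc(img, cx, cy, r, value=200.0):
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = value


class TestProjection:
    def test_single_plane_is_identity(self):
        g = np.random.default_rng(0).uniform(0, 100, (1, 32, 32))
        stack = T.FluorescenceStack(g, g.copy(), 1.0, 5.0)
        green, red = T.max_projection(stack)
        assert np.array_equal(green, g[0])

    def test_disjoint_bright_spots_both_survive(self):
        g = np.zeros((2, 32, 32))
        g[0, 5, 5] = 100.0
        g[1, 20, 20] = 150.0
        stack = T.FluorescenceStack(g, g.copy(), 1.0, 5.0)
        green, _ = T.max_projection(stack)
        assert green[5, 5] == 100.0 and green[20, 20] == 150.0

    def test_matches_brute_force_oracle(self, small_stack):
        stack, _ = small_stack
        _, red = T.max_projection(stack)
        nz, ny, nx = stack.red.shape
        brute = np.array(
            [[max(stack.red[z, y, x] for z in range(nz)) for x in range(nx)]
             for y in range(0, ny, 16)]
        )
        assert np.array_equal(red[::16], brute)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            T.FluorescenceStack(np.zeros((0, 4, 4)), np.zeros((0, 4, 4)), 1.0, 5.0)


class TestSegmentation:
    def test_two_disjoint_discs(self):
        img = np.zeros((64, 64))
        _disc(img, 15, 15, 4)
        _disc(img, 45, 45, 4)
        ps = T.segment_dead_cells(img, threshold=100.0)
        assert len(ps) == 2

    def test_pixel_bridge_split_by_open_and_watershed(self):
        img = np.zeros((64, 64))
        _disc(img, 24, 32, 5)
        _disc(img, 40, 32, 5)
        img[32, 29:36] = 200.0  # one-pixel-wide bridge between the discs
        ps = T.segment_dead_cells(img, threshold=100.0)
        assert len(ps) == 2

    def test_isolated_pixel_removed_by_open(self):
        img = np.zeros((32, 32))
        img[10, 10] = 200.0
        ps = T.segment_dead_cells(img, threshold=100.0, min_area_px=2)
        assert len(ps) == 0

    def test_all_zero_image_yields_empty_set(self):
        ps = T.segment_dead_cells(np.zeros((32, 32)))
        assert len(ps) == 0

    def test_otsu_default_threshold_recorded(self):
        img = np.zeros((64, 64))
        _disc(img, 20, 20, 4)
        ps = T.segment_dead_cells(img)
        assert 0 < ps.threshold < 200.0
        assert len(ps) == 1

    def test_single_disc_not_oversplit(self):
        img = np.zeros((64, 64))
        _disc(img, 32, 32, 7)
        assert len(T.segment_dead_cells(img, threshold=100.0)) == 1


class TestTraumaMetrics:
    def _square_roi(self, x0=10.0, y0=10.0, side=50.0):
        return T.ROIPolygon(
            np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])
        )

    def test_square_roi_arithmetic(self):
        res = T.compute_trauma(self._square_roi(), [], 1.0, 350.0)
        assert res.ita_um2 == pytest.approx(2500.0)
        assert res.itr == pytest.approx(2500.0 / 350.0)  # ~7.14

    def test_centroid_in_polygon_counting(self):
        inside = [T.Particle((20.0 + i, 20.0), 10, i + 1) for i in range(5)]
        outside = [T.Particle((100.0 + i, 100.0), 10, 6 + i) for i in range(3)]
        res = T.compute_trauma(self._square_roi(), inside + outside, 1.0, 350.0)
        assert res.dead_count == 5

    def test_ita_scales_with_pixel_size_squared(self):
        roi = self._square_roi()
        a1 = T.compute_trauma(roi, [], 0.5, 350.0).ita_um2
        a2 = T.compute_trauma(roi, [], 1.0, 350.0).ita_um2
        assert a2 == pytest.approx(4 * a1)

    def test_counting_translation_invariant(self):
        img = np.zeros((96, 96))
        for cx, cy in [(20, 20), (40, 28), (30, 50)]:
            _disc(img, cx, cy, 3)
        shifted = np.roll(img, (7, 11), axis=(0, 1))
        n0 = len(T.segment_dead_cells(img, threshold=100.0))
        n1 = len(T.segment_dead_cells(shifted, threshold=100.0))
        assert n0 == n1 == 3

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            T.ROIPolygon(np.array([[0, 0], [1, 1], [2, 2]]))  # collinear, zero area


class TestRoiProposal:
    def test_recovers_planted_void_area(self, small_stack):
        stack, truth = small_stack
        green, red = T.max_projection(stack)
        roi = T.propose_roi(green, T.segment_dead_cells(red))
        assert roi.provenance == "auto-proposed"
        assert roi.area_px == pytest.approx(truth.roi.area_px, rel=0.25)

    def test_uniform_bright_image_has_no_void(self):
        with pytest.raises(T.NoVoidError):
            T.propose_roi(np.full((64, 64), 150.0))

    def test_adjacent_red_particles_absorbed(self):
        green = np.full((96, 96), 100.0)
        yy, xx = np.mgrid[0:96, 0:96]
        void = (xx - 48) ** 2 / 15**2 + (yy - 48) ** 2 / 9**2 <= 1.0
        green[void] = 5.0
        red = np.zeros((96, 96))
        _disc(red, 66, 48, 3)  # just outside the void (edge at x=63)
        _disc(red, 48, 60, 3)
        particles = T.segment_dead_cells(red, threshold=100.0)
        roi = T.propose_roi(green, particles)
        from shapely.geometry import Point

        poly = roi.shapely
        assert all(poly.contains(Point(*p.centroid_xy)) for p in particles.particles)
        bare = T.propose_roi(green, None)
        assert poly.area > bare.shapely.area

    def test_quantify_stack_end_to_end_with_ground_truth_roi(self, small_stack):
        stack, truth = small_stack
        res = T.quantify_stack(stack, roi=truth.roi, shank_cross_section_um2=350.0)
        assert res.ita_um2 == pytest.approx(truth.hole_area_um2, rel=1e-6)
        assert res.dead_count == truth.in_roi_count
        assert res.roi_provenance == "ground-truth"


class TestWatershedResolution:
    def test_close_pairs_mostly_resolved(self):
        """Pairs closer than two radii are still split in >= 90% of fixtures."""
        rng = np.random.default_rng(7)
        resolved = 0
        n_trials = 30
        for _ in range(n_trials):
            img = np.zeros((64, 64))
            r = 4
            gap = rng.uniform(1.2 * r, 1.8 * r)  # centre distance < 2r
            ang = rng.uniform(0, np.pi)
            c0 = np.array([32.0, 32.0])
            c1 = c0 + gap * np.array([np.cos(ang), np.sin(ang)])
            _disc(img, *c0, r)
            _disc(img, *c1, r)
            if len(T.segment_dead_cells(img, threshold=100.0, min_peak_distance_px=2)) == 2:
                resolved += 1
        assert resolved >= 0.9 * n_trials

    def test_separated_puncta_recovered_exactly(self):
        _, truth = syn.gen_stack(syn.StackScenario(dead_cell_count=4, seed=13))
        stack, truth = syn.gen_stack(syn.StackScenario(dead_cell_count=4, seed=13))
        res = T.quantify_stack(stack, roi=truth.roi, shank_cross_section_um2=350.0)
        assert res.dead_count == 4
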