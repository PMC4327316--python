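import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonemap.mapping import (InsufficientReferences, RefPair,
                              SimilarityTransform, choose_refs_in_overlap,
                              diffuse_map, fit_similarity_lsq,
                              fit_similarity_two_points, global_map,
                              mapping_diagnostics, partition)
from clonemap.plate import make_grid
from clonemap.scenarios import similarity_scenario

coords = st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False)


class TestSimilarityTransform:
    def test_two_point_fit_identity(self):
        t = fit_similarity_two_points((0, 0), (1, 0), (0, 0), (1, 0))
        assert t.scale == pytest.approx(1.0)
        assert t.rotation == pytest.approx(0.0)
        assert np.allclose(t.apply(np.array([3.0, 4.0])), [3, 4])

    def test_two_point_fit_scale_and_quarter_turn(self):
        # (0,0),(1,0) -> (0,0),(0,2): scale 2, +90 deg, then (2,0) -> (0,4)
        t = fit_similarity_two_points((0, 0), (1, 0), (0, 0), (0, 2))
        assert t.scale == pytest.approx(2.0)
        assert t.rotation == pytest.approx(math.pi / 2)
        assert np.allclose(t.apply(np.array([2.0, 0.0])), [0, 4], atol=1e-12)

    def test_fit_interpolates_both_references_exactly(self):
        p1, p2 = (13.2, -4.5), (87.1, 22.9)
        q1, q2 = (400.0, 355.5), (-12.0, 64.25)
        t = fit_similarity_two_points(p1, p2, q1, q2)
        assert np.allclose(t.apply(np.array(p1)), q1, atol=1e-9)
        assert np.allclose(t.apply(np.array(p2)), q2, atol=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            fit_similarity_two_points((1, 1), (1, 1), (0, 0), (1, 0))
        with pytest.raises(ValueError, match="coincident"):
            fit_similarity_two_points((0, 0), (1, 0), (2, 2), (2, 2))

    def test_compose_hand_example(self):
        t = SimilarityTransform(2.0, 0.0, 1.0, 0.0)
        assert np.allclose(t.apply(np.array([1.0, 1.0])), [3, 2])

    def test_invert_identity_is_identity(self):
        t = SimilarityTransform.identity().invert()
        assert (t.scale, t.rotation, t.tx, t.ty) == (1.0, 0.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(s=st.floats(0.1, 10), rot=st.floats(-3, 3), tx=coords, ty=coords,
           x=coords, y=coords)
    def test_apply_then_invert_round_trips(self, s, rot, tx, ty, x, y):
        t = SimilarityTransform(s, rot, tx, ty)
        p = np.array([x, y])
        assert np.allclose(t.invert().apply(t.apply(p)), p, atol=1e-6)

    @settings(derandomize=True, max_examples=25)
    @given(s1=st.floats(0.5, 2), r1=st.floats(-1, 1), s2=st.floats(0.5, 2),
           r2=st.floats(-1, 1), x=coords, y=coords)
    def test_compose_agrees_with_sequential_application(self, s1, r1, s2, r2, x, y):
        a = SimilarityTransform(s1, r1, 5.0, -3.0)
        b = SimilarityTransform(s2, r2, -8.0, 2.0)
        p = np.array([x, y])
        assert np.allclose(a.compose(b).apply(p), a.apply(b.apply(p)), atol=1e-6)

    def test_lsq_fit_matches_two_point_fit_on_two_points(self):
        src = np.array([[0.0, 0.0], [10.0, 5.0]])
        dst = np.array([[3.0, 1.0], [-4.0, 18.0]])
        t2 = fit_similarity_two_points(src[0], src[1], dst[0], dst[1])
        tl = fit_similarity_lsq(src, dst)
        assert tl.scale == pytest.approx(t2.scale)
        assert tl.rotation == pytest.approx(t2.rotation)


class TestPartition:
    def test_single_cell_covers_bounds(self):
        g = partition((0, 0, 100, 80), 1, 1, 0.1)
        assert np.allclose(g.core[0], [0, 0, 100, 80])
        assert np.allclose(g.extended[0], [0, 0, 100, 80])  # clipped at border

    def test_default_partition_has_300_subdomains(self):
        g = partition((0, 0, 4000, 3000))
        assert g.n == 300

    def test_interior_extended_bounds_overlap_by_twice_fraction(self):
        g = partition((0, 0, 100, 100), 4, 4, 0.1)
        # interior neighbours share 2 * 0.1 * 25 = 5 units of overlap
        left, right = g.extended[5], g.extended[6]
        assert right[0] == pytest.approx(left[2] - 2 * 0.1 * 25)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            partition((0, 0, 0, 100), 2, 2, 0.1)


class TestChooseRefs:
    def test_two_candidates_returned_as_the_pair(self):
        refs = choose_refs_in_overlap(["a", "b"], [[0, 0], [5, 5]],
                                      [[0, 0], [50, 50]], [0.1, 0.2], 13.5)
        assert refs.read_ids == ("a", "b")

    def test_collinear_candidates_pick_extremes(self):
        refs = choose_refs_in_overlap(
            ["a", "b", "c"], [[0, 0], [1, 0], [10, 0]],
            [[0, 0], [50, 0], [500, 0]], [0.1, 0.1, 0.1], 13.5)
        assert refs.read_ids == ("a", "c")

    def test_high_residual_candidates_are_untrusted(self):
        with pytest.raises(InsufficientReferences):
            choose_refs_in_overlap(["a", "b"], [[0, 0], [5, 5]],
                                   [[0, 0], [50, 50]],
                                   [0.25 * 13.5, 0.25 * 13.5], 13.5)


def _pixels_frame(reads):
    return reads[["read_id", "x_px", "y_px"]]


class TestGlobalAndDiffuse:
    def test_similarity_distortion_maps_every_read_correctly(self):
        # a pure similarity is fitted exactly from two points: both the
        # one-step and the subdomain algorithm must be perfect
        reads, grid, refs, subgrid = similarity_scenario(seed=0)
        truth = reads[["read_id", "well_id"]]
        g = global_map(_pixels_frame(reads), refs, grid)
        l = diffuse_map(_pixels_frame(reads), grid, refs, subgrid)
        gd = mapping_diagnostics(g, truth)
        ld = mapping_diagnostics(l, truth)
        assert gd["misassignment_fraction"] == 0.0
        assert ld["misassignment_fraction"] == 0.0
        assert gd["residual_px"]["max"] < 1e-6 * 50
        assert ld["residual_px"]["max"] < 1e-6 * 50

    def test_diffuse_is_deterministic(self):
        reads, grid, refs, subgrid = similarity_scenario(seed=3)
        a = diffuse_map(_pixels_frame(reads), grid, refs, subgrid)
        b = diffuse_map(_pixels_frame(reads), grid, refs, subgrid)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert a.subdomain_status == b.subdomain_status

    def test_no_well_keeps_two_ok_reads_after_conflict_resolution(self):
        # force collisions: two reads at identical pixels
        grid = make_grid(5, 5, 50, "square")
        centers = grid.centers()
        pix = pd.DataFrame({
            "read_id": ["r0", "r1", "r2"],
            "x_px": [0.0, 0.0, 50.0],
            "y_px": [0.0, 0.0, 0.0],
        })
        refs = RefPair(pixels=[[0, 0], [200, 200]], wells=[[0, 0], [200, 200]])
        res = global_map(pix, refs, grid)
        ok = res.frame[res.frame["flag"] == "ok"]
        assert not ok["well_id"].duplicated().any()
        assert (res.frame["flag"] == "collision").sum() == 1

    def test_bald_subdomain_is_routed_around(self):
        # beads everywhere except the centre ninth of the chip; the wave
        # must flow around the hole and still map the far side
        grid = make_grid(30, 30, 50, "square")
        centers = grid.centers()
        rng = np.random.default_rng(5)
        occupied = rng.choice(grid.n_wells, size=300, replace=False)
        pts = centers[occupied]
        span = 30 * 50.0
        hole = ((pts[:, 0] > span / 3) & (pts[:, 0] < 2 * span / 3)
                & (pts[:, 1] > span / 3) & (pts[:, 1] < 2 * span / 3))
        pts = pts[~hole]
        occupied = occupied[~hole]
        reads = pd.DataFrame({
            "read_id": [f"r{i:04d}" for i in range(len(pts))],
            "x_px": pts[:, 0], "y_px": pts[:, 1],
            "well_id": [grid.well_id(int(w)) for w in occupied],
        })
        bounds = (pts[:, 0].min() - 1e-6, pts[:, 1].min() - 1e-6,
                  pts[:, 0].max() + 1e-6, pts[:, 1].max() + 1e-6)
        subgrid = partition(bounds, 3, 3, 0.2)
        in_first_cell = reads[(reads["x_px"] < span / 3 - 50)
                              & (reads["y_px"] < span / 3 - 50)]
        corner = in_first_cell.iloc[[0, 1]]
        refs = RefPair(pixels=corner[["x_px", "y_px"]].to_numpy(),
                       wells=centers[[grid.index_of(w) for w in corner["well_id"]]],
                       read_ids=tuple(corner["read_id"]))
        res = diffuse_map(_pixels_frame(reads), grid, refs, subgrid)
        d = mapping_diagnostics(res, reads[["read_id", "well_id"]])
        assert d["misassignment_fraction"] == 0.0
        assert d["subdomains"]["failed"] == 0

    def test_diagnostics_without_truth_has_residuals_only(self):
        reads, grid, refs, subgrid = similarity_scenario(seed=1)
        res = global_map(_pixels_frame(reads), refs, grid)
        d = mapping_diagnostics(res)
        assert "misassignment_fraction" not in d
        assert d["residual_px"]["median"] is not None
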