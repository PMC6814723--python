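"""Extents, Delaunay dispersion, hulls, elements, doublets, depth."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from clonoscope import (
    CorticalFrame,
    axis_extents,
    clone_depth_summary,
    convex_hull_volume,
    decompose_elements,
    delaunay_edge_lengths,
    detect_doublets,
    pair_distances,
    relative_depth,
    relative_dispersion,
)

from .conftest import make_cell, make_clone


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def circumsphere(p):
    """Center/radius of the sphere through 4 points (None if degenerate)."""
    a = 2 * (p[1:] - p[0])
    b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
    try:
        center = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return None, None
    return center, np.linalg.norm(p[0] - center)


def brute_force_delaunay_edges(pts):
    """Delaunay edges via empty-circumsphere tests over all tetrahedra."""
    n = len(pts)
    edges = set()
    for quad in itertools.combinations(range(n), 4):
        center, r = circumsphere(pts[list(quad)])
        if center is None:
            continue
        others = [i for i in range(n) if i not in quad]
        if all(np.linalg.norm(pts[i] - center) > r * (1 + 1e-12) for i in others):
            edges.update(
                (min(i, j), max(i, j)) for i, j in itertools.combinations(quad, 2)
            )
    return edges


def union_find_components(pts, thr):
    parent = list(range(len(pts)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(pts)), 2):
        if np.linalg.norm(pts[i] - pts[j]) <= thr:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(pts)):
        groups.setdefault(find(i), set()).add(i)
    return sorted(map(frozenset, groups.values()), key=min)


# ---------------------------------------------------------------------------
# extents / Delaunay / hull
# ---------------------------------------------------------------------------

class TestExtents:
    def test_singleton_zero(self):
        assert axis_extents(make_clone([(5, 5, 5)])) == (0, 0, 0)

    def test_dv_only(self):
        dv, ml, ap = axis_extents(make_clone([(0, 0, 0), (0, 100, 0)]))
        assert (dv, ml, ap) == (100, 0, 0)

    def test_matches_scan_oracle(self, rng):
        pts = rng.uniform(-300, 300, (10, 3))
        dv, ml, ap = axis_extents(make_clone(pts))
        assert ml == pytest.approx(np.ptp(pts[:, 0]))
        assert dv == pytest.approx(np.ptp(pts[:, 1]))
        assert ap == pytest.approx(np.ptp(pts[:, 2]))


class TestDelaunay:
    def test_regular_tetrahedron_self_triangulates(self):
        pts = np.array(
            [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float
        )
        pts *= 10 / np.linalg.norm(pts[0] - pts[1])
        res = delaunay_edge_lengths(make_clone(pts))
        assert not res.fallback
        assert len(res.lengths) == 6
        np.testing.assert_allclose(res.lengths, 10.0)

    def test_pair_falls_back_to_distance(self):
        res = delaunay_edge_lengths(make_clone([(0, 0, 0), (0, 50, 0)]))
        assert res.fallback
        np.testing.assert_allclose(res.lengths, [50.0])

    def test_coplanar_falls_back(self):
        pts = [(0, 0, 0), (10, 0, 0), (0, 10, 0), (10, 10, 0), (5, 5, 0)]
        res = delaunay_edge_lengths(make_clone(pts))
        assert res.fallback
        assert len(res.lengths) == 10  # all pairwise

    def test_singleton_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            delaunay_edge_lengths(make_clone([(0, 0, 0)]))

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_matches_circumsphere_oracle(self, n, rng):
        pts = rng.uniform(0, 100, (n, 3))
        res = delaunay_edge_lengths(make_clone(pts))
        oracle = brute_force_delaunay_edges(pts)
        oracle_lengths = np.sort(
            [np.linalg.norm(pts[i] - pts[j]) for i, j in oracle]
        )
        np.testing.assert_allclose(res.lengths, oracle_lengths, rtol=1e-9)

    def test_edge_bounds(self, rng):
        pts = rng.uniform(0, 400, (12, 3))
        clone = make_clone(pts)
        res = delaunay_edge_lengths(clone)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        iu = np.triu_indices(len(pts), 1)
        assert res.max <= d[iu].max() + 1e-9
        assert res.lengths.min() >= d[iu].min() - 1e-9


class TestConvexHull:
    def test_unit_simplex_volume(self):
        vol, degen = convex_hull_volume(
            make_clone([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        )
        assert not degen
        assert vol == pytest.approx(1 / 6)

    def test_cube_volume(self):
        corners = list(itertools.product((0.0, 10.0), repeat=3))
        vol, degen = convex_hull_volume(make_clone(corners))
        assert not degen
        assert vol == pytest.approx(1000.0)

    def test_coplanar_degenerate(self):
        vol, degen = convex_hull_volume(
            make_clone([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])
        )
        assert degen and vol == 0.0

    def test_hull_within_bounding_box_and_cubic_scaling(self, rng):
        pts = rng.uniform(0, 200, (15, 3))
        clone = make_clone(pts)
        vol, _ = convex_hull_volume(clone)
        dv, ml, ap = axis_extents(clone)
        assert vol <= dv * ml * ap + 1e-9
        vol2, _ = convex_hull_volume(make_clone(2 * pts))
        assert vol2 == pytest.approx(8 * vol)


# ---------------------------------------------------------------------------
# elements / doublets
# ---------------------------------------------------------------------------

class TestElements:
    def test_three_cells_two_elements(self):
        dec = decompose_elements(make_clone([(0, 0, 0), (0, 10, 0), (0, 50, 0)]), 20)
        assert dec.n_elements == 2
        assert dec.clustered_cells == 2
        assert sorted(len(e) for e in dec.elements) == [1, 2]

    def test_all_within_threshold_single_cluster(self):
        dec = decompose_elements(make_clone([(0, 0, 0), (0, 10, 0), (10, 0, 0)]), 20)
        assert dec.n_elements == 1 and dec.clustered_cells == 3

    def test_singleton(self):
        dec = decompose_elements(make_clone([(0, 0, 0)]), 20)
        assert dec.n_elements == 1 and dec.clustered_cells == 0

    def test_matches_union_find_oracle_on_random_clones(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 15))
            pts = rng.uniform(0, 250, (n, 3))
            thr = float(rng.uniform(20, 120))
            dec = decompose_elements(make_clone(pts), thr)
            oracle = union_find_components(pts, thr)
            got = sorted(
                (frozenset(int(cid.split("_")[1]) for cid in e) for e in dec.elements),
                key=min,
            )
            assert got == oracle

    def test_element_count_monotone_in_threshold(self, rng):
        pts = rng.uniform(0, 300, (12, 3))
        clone = make_clone(pts)
        counts = [
            decompose_elements(clone, t).n_elements for t in (1e-6, 30, 80, 200, 1e6)
        ]
        assert counts[0] == 12 and counts[-1] == 1
        assert counts == sorted(counts, reverse=True)


class TestDoublets:
    def test_close_pair_is_doublet(self):
        res = detect_doublets(make_clone([(0, 0, 0), (0, 5, 0), (0, 100, 0)]))
        assert res.doublets == [("cl0_0", "cl0_1")]
        assert res.cells_in_doublets == 2

    def test_exactly_six_micron_not_doublet(self):
        res = detect_doublets(make_clone([(0, 0, 0), (0, 6.0, 0)]))
        assert res.doublets == []

    def test_triplet_is_multiplet_not_doublet(self):
        res = detect_doublets(make_clone([(0, 0, 0), (3, 0, 0), (0, 3, 0)]))
        assert res.doublets == []
        assert len(res.multiplets) == 1 and len(res.multiplets[0]) == 3

    def test_doublets_nest_within_elements(self, rng):
        pts = np.vstack([rng.uniform(0, 200, (8, 3)), [[0, 0, 0], [0, 4, 0]]])
        clone = make_clone(pts)
        dbl = detect_doublets(clone, 6.0)
        dec = decompose_elements(clone, 60.0)
        clusters = [e for e in dec.elements if len(e) >= 2]
        for a, b in dbl.doublets:
            assert any(a in e and b in e for e in clusters)


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

@pytest.fixture
def flat_frame():
    return CorticalFrame.flat(1000.0, x_range=(0, 2000))


class TestDepth:
    def test_boundaries_and_linear_interpolation(self, flat_frame):
        assert relative_depth((500, 0.0), flat_frame) == 0.0
        assert relative_depth((500, 1000.0), flat_frame) == 1.0
        assert relative_depth((500, 250.0), flat_frame) == pytest.approx(0.25)

    def test_sloped_boundaries(self):
        frame = CorticalFrame(
            pial=[[0, 0], [1000, 100]],
            ventricular=[[0, 1000], [1000, 1100]],
        )
        # at x=500 boundaries sit at y=50 and y=1050
        assert relative_depth((500, 550.0), frame) == pytest.approx(0.5)

    def test_outside_band_raises_with_cell_id(self, flat_frame):
        cell = make_cell("deep", x=500, y=1200)
        with pytest.raises(ValueError, match="deep"):
            relative_depth(cell, flat_frame)

    def test_tolerance_clamps(self, flat_frame):
        assert relative_depth((500, -10.0), flat_frame) == 0.0

    def test_clone_summary_upper(self, flat_frame):
        clone = make_clone([(500, 200, 0), (500, 400, 0)])
        s = clone_depth_summary(clone, flat_frame)
        assert s.barycenter_depth == pytest.approx(0.3)
        assert s.upper_lower == "U"

    def test_clone_summary_lower(self, flat_frame):
        clone = make_clone([(500, 500, 0), (500, 900, 0)])
        s = clone_depth_summary(clone, flat_frame)
        assert s.barycenter_depth == pytest.approx(0.7)
        assert s.upper_lower == "L"

    def test_depth_one_clamped_into_last_bin(self, flat_frame):
        clone = make_clone([(500, 1000, 0)])
        s = clone_depth_summary(clone, flat_frame, n_bins=6)
        assert s.bin_indices.tolist() == [5]

    def test_bins_partition_thickness(self, flat_frame):
        clone = make_clone([(500, y, 0) for y in (0, 100, 300, 500, 700, 999)])
        s = clone_depth_summary(clone, flat_frame)
        assert s.bin_indices.tolist() == [0, 0, 1, 3, 4, 5]


class TestRelativeDispersion:
    def test_arithmetic(self, flat_frame):
        clone = make_clone([(500, 100, 0), (500, 300, 0), (510, 150, 0), (490, 200, 0)])
        # DV extent 200 over thickness 1000 => 20%, over 4 cells => 5 %/cell
        assert relative_dispersion(clone, flat_frame, "DV") == pytest.approx(5.0)

    def test_singleton_zero(self, flat_frame):
        assert relative_dispersion(make_clone([(500, 100, 0)]), flat_frame) == 0.0

    def test_scale_invariance(self, flat_frame, rng):
        pts = rng.uniform(100, 900, (6, 3))
        v1 = relative_dispersion(make_clone(pts), flat_frame, "DV")
        double = CorticalFrame.flat(2000.0, x_range=(0, 4000))
        v2 = relative_dispersion(make_clone(2 * pts), double, "DV")
        assert v1 == pytest.approx(v2)

    def test_unknown_axis(self, flat_frame):
        with pytest.raises(ValueError):
            relative_dispersion(make_clone([(0, 0, 0), (0, 1, 0)]), flat_frame, "XX")


class TestPairDistances:
    def test_three_four_five(self):
        clone = make_clone([(0, 0, 0), (3, 4, 0)], clone_id="p")
        for c in clone.cells:
            c.edu_positive = True
        res = pair_distances([clone], lambda c: c.edu_positive)
        assert res.distances == pytest.approx([5.0])
        assert res.flagged_clones == []

    def test_no_positive_cells(self):
        clone = make_clone([(0, 0, 0), (3, 4, 0)])
        res = pair_distances([clone], lambda c: bool(c.edu_positive))
        assert res.distances == []

    def test_three_positives_flagged(self):
        clone = make_clone([(0, 0, 0), (10, 0, 0), (0, 10, 0)], clone_id="p")
        for c in clone.cells:
            c.edu_positive = True
        res = pair_distances([clone], lambda c: c.edu_positive)
        assert len(res.distances) == 3  # n(n-1)/2
        assert res.flagged_clones == ["p"]
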