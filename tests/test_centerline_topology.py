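import numpy as np
import pytest

from canalpose import centerline_topology as topo
from canalpose.centerline_topology import PointClass
from canalpose.skeletonize import CenterlinePoints


def _points(coords, spacing=(1.0, 1.0, 1.0)):
    return CenterlinePoints(indices=np.asarray(coords, dtype=int), spacing=spacing)


def _ring_with_spur():
    """16-point digital ring (radius 3) plus a 3-point vertical spur.

    The spur attaches at (3, 0, 0); together with the diagonal adjacency
    of its first point this forms a small crossing cluster there.
    """
    ring = [(3, 0, 0), (3, 1, 0), (2, 2, 0), (1, 3, 0), (0, 3, 0), (-1, 3, 0),
            (-2, 2, 0), (-3, 1, 0), (-3, 0, 0), (-3, -1, 0), (-2, -2, 0),
            (-1, -3, 0), (0, -3, 0), (1, -3, 0), (2, -2, 0), (3, -1, 0)]
    spur = [(3, 0, 1), (3, 0, 2), (3, 0, 3)]
    coords = np.array(ring + spur) + 4  # shift to non-negative indices
    return _points(coords), len(ring)


class TestNeighborGraph:
    def test_small_cluster_all_adjacent(self):
        g = topo.neighbor_graph(_points([(0, 0, 0), (1, 0, 0), (1, 1, 1)]))
        assert set(g.edges) == {(0, 1), (0, 2), (1, 2)}

    def test_distance_exactly_two_not_adjacent(self):
        g = topo.neighbor_graph(_points([(0, 0, 0), (2, 0, 0)]))
        assert g.number_of_edges() == 0

    def test_single_point_empty_adjacency(self):
        g = topo.neighbor_graph(_points([(5, 5, 5)]))
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            topo.neighbor_graph(_points([(0, 0, 0)]), threshold=0.0)


class TestClassifyPoints:
    def test_plus_shape_center_is_crossing(self):
        pts = _points([(1, 1, 0), (0, 1, 0), (2, 1, 0), (1, 0, 0), (1, 2, 0)])
        g = topo.neighbor_graph(pts)
        classes = topo.classify_points(g)
        assert g.degree[0] == 4
        assert classes[0] is PointClass.CROSSING

    def test_collinear_chain(self):
        pts = _points([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        classes = topo.classify_points(topo.neighbor_graph(pts))
        assert classes[1] is PointClass.ORDINARY
        assert classes[0] is PointClass.TERMINAL
        assert classes[2] is PointClass.TERMINAL

    def test_isolated_point_is_discrete(self):
        pts = _points([(0, 0, 0), (1, 0, 0), (9, 9, 9)])
        classes = topo.classify_points(topo.neighbor_graph(pts))
        assert classes[2] is PointClass.DISCRETE

    def test_classes_partition_all_points(self):
        pts, _ = _ring_with_spur()
        classes = topo.classify_points(topo.neighbor_graph(pts))
        assert len(classes) == len(pts)
        assert all(isinstance(c, PointClass) for c in classes)


class TestSplitLeftRight:
    def test_two_clusters_split_at_centroid(self):
        coords = [(10, i, 0) for i in range(10)] + [(50, i, 0) for i in range(10)]
        left, right = topo.split_left_right(_points(coords))
        assert left.sum() == 10 and right.sum() == 10
        assert left[:10].all() and right[10:].all()

    def test_unilateral_input_raises(self):
        with pytest.raises(ValueError, match="unilateral"):
            topo.split_left_right(_points([(10, i, 0) for i in range(5)]))


class TestFindCanalPoles:
    def test_extremes_recovered(self):
        # anterior = max z, posterior = min y, lateral(left) = min x
        coords = [(5, 5, 5), (5, 5, 9), (5, 1, 5), (1, 5, 5), (5, 6, 5), (6, 5, 5)]
        pts = _points(coords)
        classes = np.array([PointClass.ORDINARY] * len(coords), dtype=object)
        poles = topo.find_canal_poles(pts, classes, side="left")
        assert poles["anterior"] == 1
        assert poles["posterior"] == 2
        assert poles["lateral"] == 3

    def test_right_side_lateral_is_max_x(self):
        coords = [(5, 5, 5), (5, 5, 9), (5, 1, 5), (9, 5, 5)]
        classes = np.array([PointClass.ORDINARY] * 4, dtype=object)
        poles = topo.find_canal_poles(_points(coords), classes, side="right")
        assert poles["lateral"] == 3

    def test_discrete_points_excluded(self):
        coords = [(5, 5, 5), (5, 5, 9), (5, 1, 5), (1, 5, 5), (0, 0, 30)]
        classes = np.array([PointClass.ORDINARY] * 4 + [PointClass.DISCRETE],
                           dtype=object)
        poles = topo.find_canal_poles(_points(coords), classes, side="left")
        assert poles["anterior"] == 1  # not the discrete outlier at z=30

    def test_coincident_poles_raise(self):
        coords = [(5, 1, 9), (5, 5, 5), (6, 5, 5)]  # one point is both extremes
        classes = np.array([PointClass.ORDINARY] * 3, dtype=object)
        with pytest.raises(ValueError, match="degenerate"):
            topo.find_canal_poles(_points(coords), classes, side="right")


class TestTraceFromPole:
    def test_ring_with_spur_traced_between_crossings(self):
        pts, n_ring = _ring_with_spur()
        g = topo.neighbor_graph(pts)
        classes = topo.classify_points(g)
        pole = 8  # (-3, 0, 0) + shift: diametrically opposite the junction
        assert classes[pole] is PointClass.ORDINARY
        path = topo.trace_from_pole(pole, g, classes, pts, "left", "lateral")
        assert path.end_classes[0] is PointClass.CROSSING
        assert path.end_classes[1] is PointClass.CROSSING
        # the path stays on the ring and stops at the junction cluster
        assert 5 <= len(path) <= n_ring
        interior = path.indices[1:-1]
        ring_set = {tuple(p) for p in pts.indices[:n_ring]}
        assert all(tuple(p) in ring_set for p in interior)

    def test_open_chain_traced_fully(self):
        pts = _points([(i, 0, 0) for i in range(5)])
        g = topo.neighbor_graph(pts)
        classes = topo.classify_points(g)
        path = topo.trace_from_pole(2, g, classes, pts, "left", "lateral")
        assert len(path) == 5
        assert path.end_classes == (PointClass.TERMINAL, PointClass.TERMINAL)
        xs = path.indices[:, 0].tolist()
        assert xs in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0])

    def test_trace_from_crossing_raises(self):
        pts, _ = _ring_with_spur()
        g = topo.neighbor_graph(pts)
        classes = topo.classify_points(g)
        crossing = next(i for i in range(len(pts))
                        if classes[i] is PointClass.CROSSING)
        with pytest.raises(ValueError, match="ordinary"):
            topo.trace_from_pole(crossing, g, classes, pts, "left", "lateral")

    def test_unbranched_loop_flagged(self):
        ring = [(3, 0), (3, 1), (2, 2), (1, 3), (0, 3), (-1, 3), (-2, 2),
                (-3, 1), (-3, 0), (-3, -1), (-2, -2), (-1, -3), (0, -3),
                (1, -3), (2, -2), (3, -1)]
        coords = [(x + 4, y + 4, 0) for x, y in ring]
        pts = _points(coords)
        g = topo.neighbor_graph(pts)
        classes = topo.classify_points(g)
        path = topo.trace_from_pole(0, g, classes, pts, "left", "lateral")
        assert "unbranched_loop" in path.flags
        assert len(path) == len(ring)


class TestCommonCrusTop:
    def test_highest_crossing_cluster_wins(self):
        # two junction clusters at different heights
        def plus(cx, cy, cz):
            return [(cx, cy, cz), (cx + 1, cy, cz), (cx - 1, cy, cz),
                    (cx, cy + 1, cz), (cx, cy - 1, cz)]
        coords = plus(5, 5, 40) + plus(20, 20, 25)
        pts = _points(coords)
        classes = topo.classify_points(topo.neighbor_graph(pts))
        top = topo.identify_common_crus_top(pts, classes)
        assert top[2] == 40.0

    def test_no_junction_raises(self):
        pts = _points([(i, 0, 0) for i in range(5)])
        classes = topo.classify_points(topo.neighbor_graph(pts))
        with pytest.raises(ValueError, match="junction"):
            topo.identify_common_crus_top(pts, classes)

    def test_phantom_crus_top_recovered(self, default_phantom):
        from canalpose.pipeline import extract_canal_paths
        spec, vol, truth = default_phantom
        _, crus_tops, _ = extract_canal_paths(vol)
        for side in ("left", "right"):
            err = np.linalg.norm(crus_tops[side] - truth.crus_tops[side])
            assert err <= 2 * max(vol.spacing)  # within 2 voxels


class TestPruneSkeleton:
    def test_spur_removed_canal_kept(self):
        pts, n_ring = _ring_with_spur()
        pruned, g, classes = topo.prune_skeleton(pts, min_spur=4, min_component=4)
        kept = {tuple(p) for p in pruned.indices}
        assert (3 + 4, 0 + 4, 3 + 4) not in kept  # spur tip gone
        assert (0 + 4, 3 + 4, 0 + 4) in kept      # ring survives

    def test_small_components_removed(self):
        coords = [(i, 0, 0) for i in range(20)] + [(40, 40, 40), (41, 40, 40)]
        pruned, _, _ = topo.prune_skeleton(_points(coords), min_component=5)
        assert len(pruned) == 20

    def test_clean_skeleton_unchanged(self):
        coords = [(i, 0, 0) for i in range(20)]
        pruned, _, _ = topo.prune_skeleton(_points(coords))
        assert len(pruned) == 20


class TestPhantomPaths:
    def test_paths_interior_ordinary_and_overlap_only_at_junctions(self, default_phantom):
        from canalpose.pipeline import extract_canal_paths
        _, vol, _ = default_phantom
        paths, _, qc = extract_canal_paths(vol)
        assert not qc
        assert len(paths) == 6
        for side in ("left", "right"):
            sets = {c: {tuple(p) for p in paths[(side, c)].indices[1:-1]}
                    for c in ("anterior", "posterior", "lateral")}
            for a, b in (("anterior", "posterior"), ("anterior", "lateral"),
                         ("posterior", "lateral")):
                assert not (sets[a] & sets[b])  # interiors disjoint

    def test_canal_identification_matches_truth(self, default_phantom):
        """Each traced path must lie on the arc of the canal it is named for."""
        from canalpose.pipeline import extract_canal_paths
        spec, vol, truth = default_phantom
        paths, _, _ = extract_canal_paths(vol)
        for (side, canal), path in paths.items():
            arc = spec.sides[side].canals[canal]
            q = path.points - arc.center
            a = q @ arc.normal
            qp = q - np.outer(a, arc.normal)
            d = np.hypot(np.linalg.norm(qp, axis=1) - arc.radius, a)
            assert np.median(d) < 1.5  # on-tube for the named canal
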