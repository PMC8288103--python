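"""Connectome construction: endpoint assignment, filtering, aggregation."""

import numpy as np
import pytest
import scipy.sparse as sp

from intraconn.connectome import (UNASSIGNED, assign_endpoint_to_node,
                                  build_highres_connectome,
                                  build_lowres_connectome,
                                  extract_region_subnetwork,
                                  filter_streamlines, lateralize_connectome,
                                  lateralize_region_labels, logistic_weights)
from intraconn.synthetic import StreamlineSet, SurfaceMesh


@pytest.fixture
def flat_mesh():
    """Four coplanar unit-ish triangles in two regions, easy to reason about."""
    vertices = np.array([
        [0, 0, 0], [2, 0, 0], [1, 2, 0],      # triangle 0 (region 0, L)
        [10, 0, 0], [12, 0, 0], [11, 2, 0],   # triangle 1 (region 0, L)
        [20, 0, 0], [22, 0, 0], [21, 2, 0],   # triangle 2 (region 1, R)
        [30, 0, 0], [32, 0, 0], [31, 2, 0],   # triangle 3 (region 1, R)
    ], dtype=float)
    triangles = np.arange(12).reshape(4, 3)
    return SurfaceMesh(vertices, triangles,
                       region_label=np.array([0, 0, 1, 1]),
                       hemisphere=np.array(["L", "L", "R", "R"]))


def straight(a, b):
    return np.vstack([a, 0.5 * (a + b), b])


class TestEndpointAssignment:
    def test_exact_center_hit(self, flat_mesh):
        centers = flat_mesh.triangle_center
        assert assign_endpoint_to_node(centers[2], flat_mesh) == 2

    def test_tie_broken_to_lowest_index(self, flat_mesh):
        centers = flat_mesh.triangle_center
        mid = 0.5 * (centers[1] + centers[2])
        assert assign_endpoint_to_node(mid, flat_mesh, max_dist=20.0) == 1

    def test_beyond_max_dist_unassigned(self, flat_mesh):
        far = flat_mesh.triangle_center[0] + np.array([0, 0, 5.0])
        assert assign_endpoint_to_node(far, flat_mesh, max_dist=2.0) == UNASSIGNED

    def test_empty_mesh_rejected(self):
        empty = SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), int),
                            np.empty(0, int), np.empty(0))
        with pytest.raises(ValueError, match="empty"):
            assign_endpoint_to_node(np.zeros(3), empty)

    def test_non_finite_point_rejected(self, flat_mesh):
        with pytest.raises(ValueError, match="finite"):
            assign_endpoint_to_node(np.array([np.nan, 0, 0]), flat_mesh)


class TestFilterStreamlines:
    def test_length_filter_strict(self, flat_mesh):
        c = flat_mesh.triangle_center
        sl = StreamlineSet.from_polylines([
            straight(c[0], c[0] + [5, 0, 0]),     # 5 mm: too short
            straight(c[0], c[1]),                 # 10 mm: boundary, excluded
            straight(c[0], c[2]),                 # 20 mm: retained
        ])
        retained, pairs = filter_streamlines(sl, flat_mesh, max_dist=6.0,
                                             length_bounds=(10, 300))
        assert retained.n == 1
        assert pairs.tolist() == [[0, 2]]

    def test_unassigned_endpoint_removed(self, flat_mesh):
        c = flat_mesh.triangle_center
        sl = StreamlineSet.from_polylines([
            straight(c[0] + [0, 0, 9.0], c[2]),   # first endpoint off-mesh
            straight(c[0], c[2]),
        ])
        retained, pairs = filter_streamlines(sl, flat_mesh, max_dist=2.0,
                                             length_bounds=(10, 300))
        assert retained.n == 1 and pairs.tolist() == [[0, 2]]


class TestHighResConnectome:
    def test_hand_computed_weight(self):
        """Two streamlines between equal 4 mm^2 triangles: weight = 0.5."""
        s = 2.0 * np.sqrt(2.0)  # right triangle with legs s has area 4
        vertices = np.array([
            [0, 0, 0], [s, 0, 0], [0, s, 0],
            [30, 0, 0], [30 + s, 0, 0], [30, s, 0],
        ])
        mesh = SurfaceMesh(vertices, np.arange(6).reshape(2, 3),
                           np.array([0, 1]), np.array(["L", "R"]))
        c = mesh.triangle_center
        sl = StreamlineSet.from_polylines([straight(c[0], c[1]),
                                           straight(c[1], c[0])])
        conn = build_highres_connectome(sl, mesh, max_dist=1.0,
                                        length_bounds=(10, 300))
        assert conn.counts[0, 1] == 2
        assert conn.weights[0, 1] == pytest.approx(2 / ((4 + 4) / 2))

    def test_symmetry_and_zero_diagonal(self, small_mesh, small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        assert (conn.counts != conn.counts.T).nnz == 0
        assert conn.counts.diagonal().sum() == 0
        assert (conn.weights != conn.weights.T).nnz == 0

    def test_weights_positive_iff_counts(self, small_mesh, small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        assert np.array_equal(conn.counts.nonzero(), conn.weights.nonzero())

    def test_streamline_conservation(self, small_mesh, small_streamlines):
        """Matrix entries + same-node exclusions = retained streamlines."""
        retained, pairs = filter_streamlines(small_streamlines, small_mesh)
        conn = build_highres_connectome(small_streamlines, small_mesh)
        same_node = int((pairs[:, 0] == pairs[:, 1]).sum())
        assert conn.n_streamlines_in_matrix() + same_node == retained.n

    def test_empty_input_warns(self, small_mesh):
        with pytest.warns(UserWarning, match="no streamlines"):
            conn = build_highres_connectome(
                StreamlineSet.from_polylines([]), small_mesh)
        assert conn.counts.nnz == 0


class TestLowResConnectome:
    def test_region_counts_match_brute_force(self, small_mesh,
                                             small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        low = build_lowres_connectome(conn)
        coo = sp.triu(conn.counts, k=1).tocoo()
        regions = conn.node_region
        brute = np.zeros_like(low.counts)
        for r, c, v in zip(coo.row, coo.col, coo.data):
            if regions[r] != regions[c]:
                brute[regions[r], regions[c]] += v
                brute[regions[c], regions[r]] += v
        assert np.array_equal(low.counts, brute)

    def test_logistic_map_monotone_and_bounded(self):
        counts = np.array([[0, 3, 10], [3, 0, 100], [10, 100, 0]], float)
        w = logistic_weights(counts)
        assert w[0, 0] == 0
        assert 0 < w[0, 1] < w[0, 2] < w[1, 2] < 1

    def test_zero_count_zero_weight(self, small_mesh, small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        low = build_lowres_connectome(conn)
        assert np.array_equal(low.weights == 0, low.counts == 0)

    def test_single_region_warns(self, flat_mesh):
        one = SurfaceMesh(flat_mesh.vertices, flat_mesh.triangles,
                          np.zeros(4, int), flat_mesh.hemisphere)
        c = one.triangle_center
        sl = StreamlineSet.from_polylines([straight(c[0], c[2])])
        conn = build_highres_connectome(sl, one, max_dist=1.0)
        with pytest.warns(UserWarning, match="single-region"):
            low = build_lowres_connectome(conn)
        assert low.counts.shape == (1, 1) and low.counts.sum() == 0


class TestRegionSubnetwork:
    def test_node_count_matches_region(self, small_mesh, small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        for g in conn.region_ids:
            sub = extract_region_subnetwork(conn, g)
            assert sub.n_nodes == (conn.node_region == g).sum()

    def test_matches_brute_force_induced_subgraph(self, small_mesh,
                                                  small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        g = conn.region_ids[0]
        sub = extract_region_subnetwork(conn, g)
        nodes = conn.region_nodes(g)
        dense = conn.counts.toarray()
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                expected = 1 if (u != v and dense[u, v] > 0) else 0
                assert sub.adjacency[i, j] == expected

    def test_unknown_region_rejected(self, small_mesh, small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        with pytest.raises(KeyError):
            extract_region_subnetwork(conn, 99)


class TestLateralize:
    def test_left_side_is_identity(self, small_mesh, small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        out = lateralize_connectome(conn, "L", n_pairs=2)
        assert np.array_equal(out.node_region, conn.node_region)

    def test_right_side_applied_twice_restores(self, small_mesh,
                                               small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        out = lateralize_connectome(
            lateralize_connectome(conn, "R", n_pairs=2), "R", n_pairs=2)
        assert np.array_equal(out.node_region, conn.node_region)
        assert np.array_equal(out.node_hemisphere, conn.node_hemisphere)

    def test_edges_invariant_under_lateralize(self, small_mesh,
                                              small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        out = lateralize_connectome(conn, "R", n_pairs=2)
        assert (out.counts != conn.counts).nnz == 0

    @pytest.mark.parametrize("side", ["L", "R"])
    def test_label_bijection(self, side):
        labels = lateralize_region_labels(np.arange(16), side, n_pairs=8)
        assert len(set(labels)) == 16
        assert sum(1 for x in labels if x.startswith("ipsi")) == 8
        assert sum(1 for x in labels if x.startswith("contra")) == 8

    def test_side_l_maps_left_to_ipsi(self):
        labels = lateralize_region_labels(np.array([0, 8]), "L", n_pairs=8)
        assert labels == ["ipsi_00", "contra_00"]
        labels = lateralize_region_labels(np.array([0, 8]), "R", n_pairs=8)
        assert labels == ["contra_00", "ipsi_00"]

    def test_missing_side_rejected(self, small_mesh, small_streamlines):
        conn = build_highres_connectome(small_streamlines, small_mesh)
        with pytest.raises(ValueError, match="side"):
            lateralize_connectome(conn, "none", n_pairs=2)
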