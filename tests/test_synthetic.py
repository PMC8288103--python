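"""Synthetic cohort generator: meshes, streamlines, planted effects."""

import numpy as np
import pytest
import scipy.sparse as sp

from intraconn.connectome import build_highres_connectome
from intraconn.metrics import binary_global_metrics
from intraconn.synthetic import (CohortConfig, SubjectRecord,
                                 cohort_dataframe, generate_cohort,
                                 generate_region_mesh, generate_streamlines,
                                 plant_within_region_effect,
                                 rewire_short_to_long)

from conftest import tiny_cohort_config


def bfs_component_count(mesh, region):
    """BFS oracle: number of edge-connected components of a region patch."""
    a, b = mesh.triangle_adjacency()
    mask = mesh.region_label == region
    nbr = {}
    for x, y in zip(a, b):
        if mask[x] and mask[y]:
            nbr.setdefault(x, []).append(y)
            nbr.setdefault(y, []).append(x)
    todo = set(np.where(mask)[0].tolist())
    comps = 0
    while todo:
        comps += 1
        stack = [todo.pop()]
        while stack:
            u = stack.pop()
            for v in nbr.get(u, []):
                if v in todo:
                    todo.remove(v)
                    stack.append(v)
    return comps


class TestRegionMesh:
    def test_single_region(self):
        mesh = generate_region_mesh(1, 400, seed=1)
        assert abs(mesh.n_triangles - 400) <= 40
        assert len(np.unique(mesh.region_label)) == 1

    def test_closed_mesh_topology_and_areas(self, small_mesh):
        V = len(np.unique(small_mesh.triangles))
        F = small_mesh.n_triangles
        e = np.sort(np.concatenate(
            [small_mesh.triangles[:, [0, 1]], small_mesh.triangles[:, [1, 2]],
             small_mesh.triangles[:, [2, 0]]]), axis=1)
        E = len(np.unique(e, axis=0))
        assert V - E + F == 2
        assert (small_mesh.triangle_area > 0).all()

    def test_regions_are_edge_connected(self, small_mesh):
        for region in np.unique(small_mesh.region_label):
            assert bfs_component_count(small_mesh, region) == 1

    def test_partition_and_size_report(self, mesh16):
        sizes = np.bincount(mesh16.region_label)
        assert len(sizes) == 16 and (sizes > 0).all()
        assert abs(mesh16.n_triangles - 1920) <= 192

    def test_hemisphere_mirroring(self, mesh16):
        # each region lies in one hemisphere; left j pairs with right j+8
        for g in range(16):
            tags = set(mesh16.hemisphere[mesh16.region_label == g])
            assert tags == ({"L"} if g < 8 else {"R"})

    def test_impossible_partition_rejected(self):
        with pytest.raises(ValueError, match="impossible partition"):
            generate_region_mesh(10, 20, seed=0)

    def test_mean_area_scaling(self):
        mesh = generate_region_mesh(2, 300, seed=4, mean_triangle_area=12.6)
        assert mesh.triangle_area.mean() == pytest.approx(12.6, rel=1e-6)


class TestStreamlines:
    def test_all_intra_at_fraction_one(self, small_mesh):
        sl = generate_streamlines(small_mesh, 500, 1.0, (10, 300), seed=2)
        first, last = sl.endpoints
        centers = small_mesh.triangle_center
        lab = small_mesh.region_label
        for i in range(sl.n):
            a = np.argmin(np.linalg.norm(centers - first[i], axis=1))
            b = np.argmin(np.linalg.norm(centers - last[i], axis=1))
            assert lab[a] == lab[b]

    def test_empty_set_valid(self, small_mesh):
        sl = generate_streamlines(small_mesh, 0, 0.5, (10, 300), seed=1)
        assert sl.n == 0
        assert len(sl.trajectory_length) == 0

    def test_lengths_within_bounds_exhaustive(self, small_mesh):
        sl = generate_streamlines(small_mesh, 1000, 0.5, (10, 300), seed=5)
        lengths = sl.trajectory_length
        assert lengths.min() >= 10 and lengths.max() <= 300

    def test_trajectory_length_matches_segment_sum(self, small_streamlines):
        sl = small_streamlines
        for i in range(0, sl.n, 97):
            poly = sl[i]
            manual = sum(np.linalg.norm(poly[j + 1] - poly[j])
                         for j in range(len(poly) - 1))
            assert sl.trajectory_length[i] == pytest.approx(manual, abs=1e-9)

    def test_endpoints_at_triangle_centers(self, small_mesh):
        sl = generate_streamlines(small_mesh, 50, 0.5, (10, 300), seed=6)
        first, _ = sl.endpoints
        centers = small_mesh.triangle_center
        d = np.linalg.norm(centers[None] - first[:, None], axis=2).min(axis=1)
        assert d.max() < 1e-9

    def test_invalid_fraction_rejected(self, small_mesh):
        with pytest.raises(ValueError):
            generate_streamlines(small_mesh, 10, 1.5, (10, 300), seed=0)


@pytest.fixture(scope="module")
def connectome(small_mesh, small_streamlines):
    return build_highres_connectome(small_streamlines, small_mesh)


class TestPlantedEffect:

    def test_rate_zero_is_identity(self, connectome):
        out = plant_within_region_effect(connectome, 0, 0.0, seed=1)
        assert (out.counts != connectome.counts).nnz == 0

    def test_intra_edge_count_conserved(self, connectome):
        region = 0
        nodes = connectome.region_nodes(region)
        mask = np.zeros(connectome.n_nodes, bool)
        mask[nodes] = True

        def n_intra(c):
            coo = sp.triu(c.counts, k=1).tocoo()
            return int((mask[coo.row] & mask[coo.col]).sum())

        before = n_intra(connectome)
        out = plant_within_region_effect(connectome, region, 0.6, seed=3)
        assert n_intra(out) == before

    def test_inter_region_edges_untouched(self, connectome):
        region = 1
        nodes = connectome.region_nodes(region)
        mask = np.zeros(connectome.n_nodes, bool)
        mask[nodes] = True
        out = plant_within_region_effect(connectome, region, 0.5, seed=4)
        coo_a = sp.triu(connectome.counts, k=1).tocoo()
        coo_b = sp.triu(out.counts, k=1).tocoo()
        inter_a = {(r, c) for r, c in zip(coo_a.row, coo_a.col)
                   if not (mask[r] and mask[c])}
        inter_b = {(r, c) for r, c in zip(coo_b.row, coo_b.col)
                   if not (mask[r] and mask[c])}
        assert inter_a == inter_b

    def test_rewiring_lowers_clustering_raises_length(self):
        """Monte-Carlo contrast of a geometric graph vs its rewired twin."""
        rng = np.random.default_rng(0)
        pts = rng.random((80, 2))
        centers = np.column_stack([pts, np.zeros(80)])
        d = np.linalg.norm(centers[:, None] - centers[None], axis=2)
        iu, ju = np.triu_indices(80, k=1)
        base = np.column_stack([iu, ju])[d[iu, ju] < 0.2].astype(np.int64)
        nodes = np.arange(80)
        deltas_c, deltas_len = [], []
        adj0 = np.zeros((80, 80), np.int8)
        adj0[base[:, 0], base[:, 1]] = adj0[base[:, 1], base[:, 0]] = 1
        c0 = binary_global_metrics(adj0)["C"]
        len0 = d[base[:, 0], base[:, 1]].mean()
        for seed in range(20):
            out = rewire_short_to_long(base, centers, nodes, 0.5,
                                       np.random.default_rng(seed))
            adj = np.zeros((80, 80), np.int8)
            adj[out[:, 0], out[:, 1]] = adj[out[:, 1], out[:, 0]] = 1
            deltas_c.append(binary_global_metrics(adj)["C"] - c0)
            deltas_len.append(d[out[:, 0], out[:, 1]].mean() - len0)
        assert np.mean(deltas_c) < 0
        assert np.mean(deltas_len) > 0

    def test_tiny_region_returned_unchanged_with_warning(self, connectome):
        # restrict to a fabricated connectome with an empty region
        with pytest.warns(UserWarning):
            edges = np.array([[0, 1]], dtype=np.int64)
            out = rewire_short_to_long(
                edges, np.zeros((5, 3)), np.array([3, 4]), 0.5,
                np.random.default_rng(0))
        assert np.array_equal(out, edges)


class TestCohort:
    def test_table1_marginals(self, default_cohort):
        df = cohort_dataframe(default_cohort[0])
        assert (df.group == "control").sum() == 36
        pat = df[df.group == "patient"]
        assert len(pat) == 33
        assert (pat.side == "L").sum() == 19 and (pat.side == "R").sum() == 14
        assert (pat.outcome <= 2).sum() == 21 and (pat.outcome > 2).sum() == 12
        assert (df[df.group == "control"].sex == "M").sum() == 17
        assert (pat[pat.side == "L"].sex == "M").sum() == 7
        assert (pat[pat.side == "R"].sex == "M").sum() == 8
        assert pat.duration.min() >= 1.0

    def test_same_seed_bit_identical(self):
        cfg = tiny_cohort_config()
        a, _ = generate_cohort(cfg, seed=3)
        b, _ = generate_cohort(cfg, seed=3)
        for (ra, ma, sa), (rb, mb, sb) in zip(a, b):
            assert ra == rb
            assert np.array_equal(ma.vertices, mb.vertices)
            assert np.array_equal(sa.points, sb.points)

    def test_different_seeds_differ(self):
        cfg = tiny_cohort_config()
        a, _ = generate_cohort(cfg, seed=3)
        b, _ = generate_cohort(cfg, seed=4)
        assert not np.array_equal(a[0][2].points, b[0][2].points)

    def test_null_configuration_plants_nothing(self):
        cfg = tiny_cohort_config(baseline_rate=0.0, duration_slope=0.0,
                                 outcome_rate=0.0, rate_noise_sd=0.0)
        subjects, truth = generate_cohort(cfg, seed=5)
        for sid, rates in truth.affected_regions.items():
            assert all(r == 0.0 for r in rates.values())

    def test_controls_have_empty_affected_set(self, default_cohort):
        _, truth = default_cohort
        for sid, rates in truth.affected_regions.items():
            if sid.startswith("C"):
                assert rates == {}

    def test_planted_rate_monotone_in_duration(self, default_cohort):
        """Earliest-onset region's rate grows with disease duration."""
        from scipy.stats import spearmanr

        subjects, truth = default_cohort
        durations, rates = [], []
        for rec, _, _ in subjects:
            if rec.group != "patient":
                continue
            region = truth.duration_regions[rec.id][0]  # onset at 0 years
            durations.append(rec.duration)
            rates.append(truth.rate(rec.id, region))
        rho, _ = spearmanr(durations, rates)
        assert rho > 0.8

    def test_bad_outcome_regions_broader(self, default_cohort):
        subjects, truth = default_cohort
        for rec, _, _ in subjects:
            if rec.group != "patient":
                continue
            planted = set(truth.affected_regions[rec.id])
            contra = set(truth.outcome_regions[rec.id])
            if rec.good_outcome:
                assert not (planted & contra)
            else:
                assert contra <= planted

    def test_invalid_patient_record_rejected(self):
        with pytest.raises(ValueError, match="surgery side"):
            SubjectRecord(id="P1", group="patient", age=30, sex="M",
                          side="none", duration=5, outcome=1)
        with pytest.raises(ValueError, match="must not carry"):
            SubjectRecord(id="C1", group="control", age=30, sex="F",
                          side="L")

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_controls=-1)
        with pytest.raises(ValueError):
            CohortConfig(n_regions=5)
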