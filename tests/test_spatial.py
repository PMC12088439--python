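import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catm.orientation import rotation_from_axis
from catm.particles import ParticleSet
from catm.simulate import planted_condensate
from catm.spatial import (SphereSurface, assortativity, build_contact_graph,
                          cluster_fraction_vs_depth, cluster_size_distribution,
                          dbscan_clusters, fit_plane, fit_sphere,
                          normalized_entropy, surface_distance_and_normal,
                          valence_distribution)


def _sphere_points(n, center, radius, rng, sigma=0.0):
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = center + radius * u
    if sigma:
        pts = pts + rng.normal(0, sigma, size=pts.shape)
    return pts


class TestSphereFit:
    def test_exact_points_recovered(self, rng):
        pts = _sphere_points(100, np.zeros(3), 500.0, rng)
        s = fit_sphere(pts)
        assert np.linalg.norm(s.center) < 1e-6 * 500
        assert s.radius == pytest.approx(500.0, rel=1e-6)

    def test_noisy_radius_within_one_percent(self, rng):
        # parameter recovery: n=500, sigma = 5 nm (= 1% of r)
        pts = _sphere_points(500, np.array([30.0, -40, 10]), 500.0, rng,
                             sigma=5.0)
        s = fit_sphere(pts)
        assert s.radius == pytest.approx(500.0, rel=0.01)
        assert s.rms_residual < 10.0

    def test_coplanar_points_rejected(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, 20), rng.uniform(0, 10, 20),
                               np.full(20, 3.0)])
        with pytest.raises(ValueError, match="underdetermined"):
            fit_sphere(pts)

    def test_radius_estimate_unbiased(self, rng):
        # bias over repeated fits < 1% at sigma = 1% of r
        radii = []
        for _ in range(10):
            pts = _sphere_points(500, np.zeros(3), 200.0, rng, sigma=2.0)
            radii.append(fit_sphere(pts).radius)
        assert np.mean(radii) == pytest.approx(200.0, rel=0.01)


class TestSurfaceGeometry:
    S = SphereSurface(np.array([0.0, 0, 0]), 100.0)

    def test_point_on_surface(self):
        d, n = surface_distance_and_normal([100.0, 0, 0], self.S)
        assert d == pytest.approx(0.0)
        np.testing.assert_allclose(n, [1, 0, 0])

    def test_interior_point_positive_depth(self):
        d, n = surface_distance_and_normal([0.0, 0, 50.0], self.S)
        assert d == pytest.approx(50.0)
        np.testing.assert_allclose(n, [0, 0, 1])

    def test_exterior_point_negative_depth(self):
        d, _ = surface_distance_and_normal([0.0, 0, 130.0], self.S)
        assert d == pytest.approx(-30.0)

    def test_center_rejected(self):
        with pytest.raises(ValueError):
            surface_distance_and_normal([0.0, 0, 0], self.S)

    def test_plane_fit(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, 30), rng.uniform(0, 10, 30),
                               np.full(30, 7.0)])
        _, n = fit_plane(pts)
        assert abs(n[2]) == pytest.approx(1.0, abs=1e-9)


def _stacked_pair(spacing):
    rows = [{"x": 0.0, "y": 0, "z": 0.0}, {"x": 0.0, "y": 0, "z": spacing}]
    return ParticleSet(pd.DataFrame(rows))


class TestContactGraph:
    def test_stacked_discs_make_contact(self):
        g = build_contact_graph(_stacked_pair(6.0), gap_threshold=1.0)
        assert g.has_edge(0, 1)

    def test_distant_discs_no_contact(self):
        g = build_contact_graph(_stacked_pair(30.0), gap_threshold=1.0)
        assert g.number_of_edges() == 0

    def test_symmetric_edges(self):
        g = build_contact_graph(_stacked_pair(6.0))
        assert g.has_edge(1, 0)

    def test_lattice_coordination_number(self):
        # square lattice of coplanar, coaxial discs at spacing just above one
        # diameter: interior nodes touch their 4 in-plane neighbors only
        rows = [{"x": 11.5 * i, "y": 11.5 * j, "z": 0.0}
                for i in range(4) for j in range(4)]
        g = build_contact_graph(ParticleSet(pd.DataFrame(rows)),
                                gap_threshold=1.0)
        degs = dict(g.degree())
        interior = [i * 4 + j for i in (1, 2) for j in (1, 2)]
        assert all(degs[n] == 4 for n in interior)

    def test_center_criterion(self):
        g = build_contact_graph(_stacked_pair(10.0), criterion="center",
                                center_threshold=12.0)
        assert g.has_edge(0, 1)
        assert g.graph["criterion"] == "center"


class TestValenceAndEntropy:
    def test_edgeless_graph(self):
        import networkx as nx
        g = nx.empty_graph(5)
        vd = valence_distribution(g)
        assert vd[0] == 1.0

    def test_triangle(self):
        import networkx as nx
        vd = valence_distribution(nx.complete_graph(3))
        assert vd[2] == 1.0

    def test_path_of_three(self):
        import networkx as nx
        vd = valence_distribution(nx.path_graph(3))
        assert vd[1] == pytest.approx(2 / 3)
        assert vd[2] == pytest.approx(1 / 3)

    def test_entropy_uniform_is_one(self):
        assert normalized_entropy([0.25, 0.25, 0.25, 0.25]) == pytest.approx(1.0)

    def test_entropy_degenerate_is_zero(self):
        assert normalized_entropy([0.0, 1.0, 0.0]) == pytest.approx(0.0)
        assert normalized_entropy([1.0]) == 0.0

    def test_entropy_two_category_value(self):
        # direct formula: H(0.75, 0.25)/log 2
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25)) / np.log(2)
        assert normalized_entropy([0.75, 0.25]) == pytest.approx(expected)
        assert expected == pytest.approx(0.8113, abs=1e-4)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_entropy_bounded(self, weights):
        h = normalized_entropy(weights)
        assert 0.0 <= h <= 1.0 + 1e-12

    def test_observed_support_convention(self):
        # (0.5, 0, 0.5): contiguous K=3, observed K=2 (-> exactly uniform)
        assert normalized_entropy([0.5, 0.0, 0.5], "observed") == pytest.approx(1.0)
        assert normalized_entropy([0.5, 0.0, 0.5]) == pytest.approx(
            np.log(2) / np.log(3))


class TestAssortativity:
    def test_disconnected_monochromatic_cliques(self):
        import networkx as nx
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        nx.set_node_attributes(g, {n: ("a" if n < 4 else "b") for n in g},
                               "class")
        assert assortativity(g) == pytest.approx(1.0)

    def test_bipartite_matches_mixing_matrix_formula(self):
        import networkx as nx
        g = nx.complete_bipartite_graph(3, 4)
        nx.set_node_attributes(g, {n: ("a" if n < 3 else "b") for n in g},
                               "class")
        # closed-form oracle: r = (tr e - sum_i a_i b_i) / (1 - sum_i a_i b_i)
        # with all 12 edges between classes: e_aa = e_bb = 0,
        # e_ab = e_ba = 0.5, so a = b = (0.5, 0.5) and r = -1
        e = np.array([[0.0, 0.5], [0.5, 0.0]])
        a, b = e.sum(axis=1), e.sum(axis=0)
        oracle = (np.trace(e) - (a * b).sum()) / (1 - (a * b).sum())
        assert assortativity(g) == pytest.approx(oracle)

    def test_shuffled_labels_near_zero(self, rng):
        import networkx as nx
        g = nx.gnm_random_graph(400, 2000, seed=3)
        nx.set_node_attributes(g, {n: int(rng.integers(2)) for n in g}, "class")
        assert abs(assortativity(g)) < 0.08

    def test_single_class_undefined(self):
        import networkx as nx
        g = nx.complete_graph(4)
        nx.set_node_attributes(g, {n: "a" for n in g}, "class")
        with pytest.warns(UserWarning):
            assert np.isnan(assortativity(g))


from tests_support import brute_force_dbscan as _brute_force_dbscan


class TestDbscan:
    def test_two_separated_blobs(self, rng):
        pts = np.vstack([rng.normal(0, 3, (50, 3)),
                         rng.normal(100, 3, (50, 3))])
        labels = dbscan_clusters(pts, eps=12.0, min_pts=3)
        assert len(set(labels)) == 2 and -1 not in labels

    def test_sparse_points_all_noise(self, rng):
        pts = rng.uniform(0, 1000, (40, 3))
        labels = dbscan_clusters(pts, eps=5.0, min_pts=10)
        assert np.all(labels == -1)

    def test_matches_brute_force_reference(self, rng):
        pts = np.vstack([rng.normal(0, 4, (30, 3)), rng.normal(40, 4, (20, 3)),
                         rng.uniform(-50, 100, (15, 3))])
        got = dbscan_clusters(pts, eps=10.0, min_pts=4)
        ref = _brute_force_dbscan(pts, 10.0, 4)
        # same noise set; same partition up to label renaming (border-point
        # ties broken identically because sklearn also assigns borders to
        # the first-discovered core cluster at these separations)
        assert np.array_equal(got == -1, ref == -1)
        from sklearn.metrics import adjusted_rand_score
        mask = got >= 0
        assert adjusted_rand_score(got[mask], ref[mask]) == 1.0

    def test_permutation_invariant_up_to_relabel(self, rng):
        pts = np.vstack([rng.normal(0, 3, (25, 3)), rng.normal(60, 3, (25, 3))])
        perm = rng.permutation(len(pts))
        a = dbscan_clusters(pts, 12.0, 3)
        b = dbscan_clusters(pts[perm], 12.0, 3)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a[perm], b) == 1.0


class TestClusterStatistics:
    def test_cumulative_size_distribution(self):
        labels = np.array([0] * 4 + [1] * 4 + [2] * 20 + [-1] * 3)
        df = cluster_size_distribution(labels)
        assert df["size"].tolist() == [4, 20]
        assert df.cumulative_fraction.tolist() == pytest.approx([2 / 3, 1.0])

    def test_no_clusters_warns(self):
        with pytest.warns(UserWarning, match="no clusters"):
            df = cluster_size_distribution(np.full(5, -1))
        assert df.empty

    def test_all_clustered_fraction_one(self, rng):
        s = SphereSurface(np.zeros(3), 100.0)
        pts = rng.normal(0, 20, (60, 3))
        labels = np.zeros(60, dtype=int)
        prof = cluster_fraction_vs_depth(pts, labels, s, bin_width=20.0)
        occupied = prof[prof.n > 0]
        assert np.all(occupied.clustered_fraction == 1.0)

    def test_low_count_bins_flagged_not_zero_division(self, rng):
        s = SphereSurface(np.zeros(3), 100.0)
        pts = np.array([[0.0, 0, 95.0]])  # one shallow particle
        prof = cluster_fraction_vs_depth(pts, np.array([-1]), s, bin_width=10.0)
        assert prof[prof.n == 0].low_count.all()
        assert prof[prof.n == 0].clustered_fraction.isna().all()

    def test_planted_shell_depletion(self):
        parts, center, radius, planted = planted_condensate(seed=2)
        s = SphereSurface(np.asarray(center), radius)
        labels = dbscan_clusters(parts, eps=12.0, min_pts=3)
        prof = cluster_fraction_vs_depth(parts, labels, s, bin_width=20.0)
        shallow = prof[(prof.depth_lo >= 0) & (prof.depth_hi <= 20) & (prof.n > 0)]
        deep = prof[(prof.depth_lo >= 40) & (prof.n > 0)]
        assert shallow.clustered_fraction.mean() < deep.clustered_fraction.mean()


class TestPlantedCondensate:
    def test_contact_graph_recovers_planted_valences(self):
        parts, _, _, planted = planted_condensate(seed=1)
        g = build_contact_graph(parts, gap_threshold=1.0)
        vd = valence_distribution(g)
        counts = (vd * len(parts)).round().astype(int)
        assert dict(counts[counts > 0]) == planted["valence_counts"]

    def test_entropy_matches_planted_distribution(self):
        parts, _, _, planted = planted_condensate(seed=1)
        g = build_contact_graph(parts)
        obs = normalized_entropy(valence_distribution(g))
        vc = planted["valence_counts"]
        p = np.zeros(max(vc) + 1)
        for k, v in vc.items():
            p[k] = v
        assert obs == pytest.approx(normalized_entropy(p / p.sum()), abs=0.02)

    def test_cluster_size_mode_recovered(self):
        parts, _, _, planted = planted_condensate(seed=1)
        labels = dbscan_clusters(parts, eps=12.0, min_pts=3)
        df = cluster_size_distribution(labels)
        mode = df.loc[df["count"].idxmax(), "size"]
        sizes, counts = np.unique(planted["cluster_sizes"], return_counts=True)
        assert mode == sizes[np.argmax(counts)]

    def test_random_labels_mix_assortatively_neutral(self):
        parts, _, _, _ = planted_condensate(seed=3, label_mode="by_motif")
        g = build_contact_graph(parts)
        # every stack is monochromatic, so same-class contact is perfect
        assert assortativity(g) == pytest.approx(1.0)
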