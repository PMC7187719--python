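"""Topology metrics vs brute-force oracles; HQS null model; normalization."""

import networkx as nx
import numpy as np
import pytest

from morphnet import (characteristic_path_length, clustering_coefficient,
                      hqs_null_covariance, maslov_sneppen_null, modularity,
                      modularity_quality, normalized_metrics)
from morphnet.netbuild import DensityGrid, threshold_to_density

from _oracles import (brute_clustering, brute_path_length, exhaustive_modularity,
                      partition_quality)


class TestClustering:
    def test_complete_graph_is_fully_clustered(self):
        assert clustering_coefficient(nx.complete_graph(4)) == 1.0

    def test_star_has_no_triangles(self):
        assert clustering_coefficient(nx.star_graph(3)) == 0.0

    def test_matches_triangle_enumeration_on_random_graphs(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(10, rng.uniform(0.2, 0.8),
                                    seed=int(rng.integers(2 ** 31)))
            assert clustering_coefficient(g) == pytest.approx(
                brute_clustering(g), abs=1e-12)


class TestPathLength:
    def test_complete_graph_has_unit_paths(self):
        assert characteristic_path_length(nx.complete_graph(7)) == 1.0

    def test_path_graph_enumeration(self):
        # P4 pair distances: 1+2+3+1+2+1 = 10 over 6 pairs
        assert characteristic_path_length(nx.path_graph(4)) == pytest.approx(10 / 6)

    def test_matches_floyd_warshall_oracle(self, rng):
        done = 0
        while done < 15:
            g = nx.gnp_random_graph(12, rng.uniform(0.25, 0.7),
                                    seed=int(rng.integers(2 ** 31)))
            if not nx.is_connected(g):
                continue
            done += 1
            assert characteristic_path_length(g) == pytest.approx(
                brute_path_length(g), abs=1e-12)

    def test_disconnected_graph_is_an_explicit_error(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="disconnected"):
            characteristic_path_length(g)


class TestModularity:
    def test_single_community_of_complete_graph_scores_zero(self):
        g = nx.complete_graph(5)
        assert modularity_quality(g, [set(range(5))]) == pytest.approx(0.0, abs=1e-12)
        q, _ = modularity(g, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_reach_the_exhaustive_maximum(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        q, partition = modularity(g, seed=1)
        assert q == pytest.approx(exhaustive_modularity(g), abs=1e-12)
        assert {frozenset(c) for c in partition} == {
            frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})}

    def test_quality_function_matches_hand_arithmetic(self):
        # bowtie: triangle {0,1,2} + triangle {2,3,4}; partition at node 2
        g = nx.Graph([(0, 1), (0, 2), (1, 2), (2, 3), (2, 4), (3, 4)])
        part = [{0, 1, 2}, {3, 4}]
        # m=6; e1=3, d1=2+2+4=8; e2=1, d2=2+2=4
        expected = (3 / 6 - (8 / 12) ** 2) + (1 / 6 - (4 / 12) ** 2)
        assert modularity_quality(g, part) == pytest.approx(expected, abs=1e-12)
        assert partition_quality(g, part) == pytest.approx(expected, abs=1e-12)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            modularity(nx.empty_graph(4), seed=0)

    def test_seeded_determinism(self, modular_ct_network):
        g = threshold_to_density(modular_ct_network, 0.2)
        q1, p1 = modularity(g, seed=5)
        q2, p2 = modularity(g, seed=5)
        assert q1 == q2 and p1 == p2


class TestHQSNull:
    def make_uniform_net(self, n=30, c=0.3):
        m = np.full((n, n), c)
        np.fill_diagonal(m, 1.0)
        return m

    def test_offdiagonal_mean_is_matched(self):
        m = self.make_uniform_net(c=0.3)
        means = []
        for k in range(100):
            null = hqs_null_covariance(m, seed=k)
            iu = np.triu_indices(30, 1)
            means.append(null[iu].mean())
        assert abs(np.mean(means) - 0.3) < 0.02

    def test_positive_semidefinite_by_construction(self, modular_ct_network):
        null = hqs_null_covariance(modular_ct_network, seed=3)
        assert np.linalg.eigvalsh(null).min() >= -1e-10

    def test_same_seed_reproduces_the_matrix(self, modular_ct_network):
        a = hqs_null_covariance(modular_ct_network, seed=9)
        b = hqs_null_covariance(modular_ct_network, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_symmetry(self, modular_ct_network):
        null = hqs_null_covariance(modular_ct_network, seed=1)
        np.testing.assert_allclose(null, null.T, atol=1e-12)

    def test_negative_mean_covariance_rejected(self):
        m = np.full((5, 5), -0.3)
        np.fill_diagonal(m, 1.0)
        m += np.diag(np.zeros(5))
        m[0, 1] = m[1, 0] = -0.2  # nonzero variance
        with pytest.raises(ValueError, match="negative"):
            hqs_null_covariance(m, seed=0)

    def test_constant_matrix_still_matches_the_mean(self):
        # degenerate zero-variance target: factor count is capped, the
        # off-diagonal mean is still reproduced
        null = hqs_null_covariance(self.make_uniform_net(n=8, c=0.5), seed=0)
        iu = np.triu_indices(8, 1)
        assert abs(null[iu].mean() - 0.5) < 0.05


class TestNormalizedMetrics:
    def test_self_null_normalizes_to_unity(self, modular_ct_network):
        rec = normalized_metrics(
            modular_ct_network, grid=DensityGrid(0.5, 3), n_null=1, seed=0,
            n_restarts=2, null_generator=lambda net, seed: net.matrix)
        np.testing.assert_allclose(rec["gamma"], 1.0, atol=1e-12)
        np.testing.assert_allclose(rec["lambda"], 1.0, atol=1e-12)
        np.testing.assert_allclose(rec["sigma"], 1.0, atol=1e-12)

    def test_sigma_is_exactly_gamma_over_lambda(self, modular_ct_network):
        rec = normalized_metrics(modular_ct_network, grid=DensityGrid(0.5, 4),
                                 n_null=5, seed=2, n_restarts=2)
        np.testing.assert_array_equal(rec["sigma"],
                                      rec["gamma"] / rec["lambda"])

    def test_watts_strogatz_regime_is_small_world(self):
        # ring lattice with light rewiring vs degree-matched rewired nulls
        g = nx.watts_strogatz_graph(30, 4, 0.1, seed=42)
        cp, lp = clustering_coefficient(g), characteristic_path_length(g)
        from morphnet.graphmetrics import _largest_component_path_length
        null_cp, null_lp = [], []
        for k in range(20):
            h = maslov_sneppen_null(g, seed=k)
            null_cp.append(clustering_coefficient(h))
            null_lp.append(_largest_component_path_length(h)[0])
        gamma = cp / np.mean(null_cp)
        lam = lp / np.mean(null_lp)
        assert gamma / lam > 1.0
        assert gamma > 1.0

    def test_unstructured_network_normalizes_near_unity(self, rng):
        # near-uniform correlation: thresholded graph is ER-like, so the
        # moment-matched nulls should reproduce Cp and Lp closely
        x = rng.normal(size=(60, 40)) + 0.35 * rng.normal(size=(60, 1))
        m = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(m, 1.0)
        rec = normalized_metrics(m, grid=DensityGrid(0.5, 2), n_null=100,
                                 seed=4, n_restarts=2)
        assert np.all(np.abs(rec["gamma"] - 1.0) < 0.15)
        assert np.all(np.abs(rec["lambda"] - 1.0) < 0.15)

    def test_path_length_non_increasing_with_density(self, modular_ct_network):
        rec = normalized_metrics(modular_ct_network, grid=DensityGrid(0.5, 10),
                                 n_null=2, seed=6, n_restarts=2)
        assert (np.diff(rec["Lp"]) <= 1e-12).all()

    def test_disconnected_observed_graph_is_an_error(self):
        m = np.eye(6)
        m[np.ix_([0, 1, 2], [0, 1, 2])] = 0.9
        m[np.ix_([3, 4, 5], [3, 4, 5])] = 0.8
        np.fill_diagonal(m, 1.0)
        m[0, 3] = m[3, 0] = 0.05
        with pytest.raises(ValueError, match="disconnected"):
            normalized_metrics(m, grid=DensityGrid(0.4, 1), n_null=2, seed=0,
                               n_restarts=2)


def test_optional_null_normalized_modularity(modular_ct_network):
    rec = normalized_metrics(modular_ct_network, grid=DensityGrid(0.5, 2),
                             n_null=3, seed=1, n_restarts=2, normalize_q=True)
    assert {"Qrand_p", "Q_norm"} <= set(rec.columns)
    np.testing.assert_allclose(rec["Q_norm"], rec["Q"] / rec["Qrand_p"])
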