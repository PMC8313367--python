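import itertools

import numpy as np
import pytest

from dfcstates.graph import (
    characteristic_path_length,
    clustering_coefficient,
    degree,
    detect_modules,
    global_efficiency,
    local_efficiency,
    participation_coefficient,
    shortest_path_lengths,
    state_metrics,
    threshold_state,
    within_module_zscore,
)


def binary_graph(adj):
    a = np.asarray(adj, dtype=float)
    return threshold_state(a, tau=0.5, mode="binary")


def graph_from_edges(n, edges):
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return binary_graph(a)


class TestThreshold:
    def test_all_subthreshold_empty(self):
        g = threshold_state(np.full((4, 4), 0.2), tau=0.3)
        assert g.adjacency.sum() == 0 and g.sparsity == 0

    def test_all_suprathreshold_complete(self):
        a = np.full((4, 4), 0.5)
        np.fill_diagonal(a, 0)
        g = threshold_state(a, tau=0.3)
        assert g.sparsity == 1.0

    def test_strictly_below_removed_negatives_included(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.5
        a[0, 2] = a[2, 0] = 0.29
        a[1, 2] = a[2, 1] = -0.2
        a[2, 3] = a[3, 2] = 0.31
        g = threshold_state(a, tau=0.3, mode="weighted")
        survivors = sorted(g.adjacency[np.triu_indices(4, 1)][g.adjacency[np.triu_indices(4, 1)] > 0])
        assert survivors == [0.31, 0.5]

    def test_binary_maps_survivors_to_one(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.9
        g = threshold_state(a, tau=0.3, mode="binary")
        assert set(np.unique(g.adjacency)) <= {0.0, 1.0}


class TestDegree:
    def test_star_graph(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert degree(g).tolist() == [3, 1, 1, 1]

    def test_weighted_triangle(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.4
        a[1, 2] = a[2, 1] = 0.6
        a[0, 2] = a[2, 0] = 0.5
        g = threshold_state(a, tau=0.3, mode="weighted")
        assert np.allclose(degree(g), [0.9, 1.0, 1.1])

    def test_empty_graph(self):
        g = graph_from_edges(3, [])
        assert degree(g).tolist() == [0, 0, 0]


class TestSmallGraphValues:
    def test_triangle_clustering(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        cc, mean_cc = clustering_coefficient(g)
        assert np.allclose(cc, 1.0) and mean_cc == 1.0

    def test_path_clustering_zero(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        cc, _ = clustering_coefficient(g)
        assert np.allclose(cc, 0.0)

    def test_path_distances_and_cpl(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        d = shortest_path_lengths(g)
        assert d[0, 2] == 2 and d[0, 0] == 0
        cpl, excluded = characteristic_path_length(d)
        assert cpl == pytest.approx(4 / 3) and excluded == 0

    def test_complete_graph_cpl_and_eglob(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        d = shortest_path_lengths(g)
        assert characteristic_path_length(d)[0] == 1.0
        assert global_efficiency(d) == 1.0

    def test_disconnected_pairs(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        d = shortest_path_lengths(g)
        assert np.isinf(d[0, 2])
        cpl, excluded = characteristic_path_length(d)
        assert cpl == 1.0 and excluded == 8
        assert global_efficiency(shortest_path_lengths(graph_from_edges(3, []))) == 0.0

    def test_p3_global_efficiency(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert global_efficiency(shortest_path_lengths(g)) == pytest.approx(5 / 6)

    def test_local_efficiency_k4_and_star(self):
        k4 = graph_from_edges(4, list(itertools.combinations(range(4), 2)))
        e, mean_e = local_efficiency(k4)
        assert np.allclose(e, 1.0) and mean_e == 1.0
        star = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        e, mean_e = local_efficiency(star)
        assert np.allclose(e, 0.0)


class TestModulesAndHubs:
    def test_two_cliques_split(self):
        edges = list(itertools.combinations(range(4), 2)) + [
            (i + 4, j + 4) for i, j in itertools.combinations(range(4), 2)
        ] + [(3, 4)]
        g = graph_from_edges(8, edges)
        partition, q = detect_modules(g, seed=0)
        assert len(np.unique(partition)) == 2
        assert len(np.unique(partition[:4])) == 1
        assert len(np.unique(partition[4:])) == 1
        assert q > 0.3

    def test_two_cliques_beats_exhaustive_bipartitions(self):
        """Louvain Q matches the best Q over all bipartitions of 8 nodes."""
        import networkx as nx

        edges = list(itertools.combinations(range(4), 2)) + [
            (i + 4, j + 4) for i, j in itertools.combinations(range(4), 2)
        ] + [(3, 4)]
        g = graph_from_edges(8, edges)
        nxg = nx.from_numpy_array(g.adjacency)
        best = -1.0
        for mask in range(1, 2**7):  # node 0 fixed in part A
            a = {i for i in range(8) if (mask >> i) & 1 == 0}
            b = set(range(8)) - a
            if a and b:
                best = max(best, nx.community.modularity(nxg, [a, b]))
        _, q = detect_modules(g, seed=0)
        assert q == pytest.approx(best, abs=1e-12)

    def test_complete_graph_no_structure(self):
        g = graph_from_edges(5, list(itertools.combinations(range(5), 2)))
        _, q = detect_modules(g, seed=0)
        assert q == pytest.approx(0.0, abs=0.05)

    def test_empty_graph_singletons(self):
        partition, q = detect_modules(graph_from_edges(4, []), seed=0)
        assert q == 0.0 and len(np.unique(partition)) == 4

    def test_participation_examples(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        p = participation_coefficient(g, [0, 0, 1, 1])
        assert np.allclose(p, 0.0)
        g2 = graph_from_edges(3, [(0, 1), (0, 2)])
        p2 = participation_coefficient(g2, [0, 0, 1])
        assert p2[0] == pytest.approx(1 - (0.5**2 + 0.5**2))

    def test_zscore_regular_and_uneven_module(self):
        ring = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert np.allclose(within_module_zscore(ring, [0, 0, 0, 0]), 0.0)
        # within-degrees (2,1,1): population sd oracle
        tri = graph_from_edges(3, [(0, 1), (0, 2)])
        kappa = np.array([2.0, 1.0, 1.0])
        expected = (kappa - kappa.mean()) / kappa.std()
        assert np.allclose(within_module_zscore(tri, [0, 0, 0]), expected)

    def test_singleton_module_zero(self):
        g = graph_from_edges(3, [(0, 1)])
        z = within_module_zscore(g, [0, 0, 1])
        assert z[2] == 0.0


def random_binary_graph(rng, n):
    a = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < rng.uniform(0.2, 0.8)
    a[iu] = mask
    a += a.T
    return binary_graph(a)


class TestProperties:
    def test_isomorphism_invariance(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            g = random_binary_graph(rng, n)
            perm = rng.permutation(n)
            gp = binary_graph(g.adjacency[np.ix_(perm, perm)])
            assert np.allclose(degree(gp), degree(g)[perm])
            cc, mean_cc = clustering_coefficient(g)
            ccp, mean_ccp = clustering_coefficient(gp)
            assert np.allclose(ccp, cc[perm]) and mean_cc == pytest.approx(mean_ccp)
            d, dp = shortest_path_lengths(g), shortest_path_lengths(gp)
            assert characteristic_path_length(d)[0] == pytest.approx(
                characteristic_path_length(dp)[0], nan_ok=True
            )
            assert global_efficiency(d) == pytest.approx(global_efficiency(dp))

    def test_adding_edge_monotone(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            g = random_binary_graph(rng, n)
            a = g.adjacency.copy()
            missing = np.argwhere((a == 0) & ~np.eye(n, dtype=bool))
            if missing.size == 0:
                continue
            i, j = missing[rng.integers(len(missing))]
            a[i, j] = a[j, i] = 1.0
            d0, d1 = (
                shortest_path_lengths(g),
                shortest_path_lengths(binary_graph(a)),
            )
            assert global_efficiency(d1) >= global_efficiency(d0) - 1e-12
            # distances can only shrink entrywise
            assert np.all(d1 <= d0 + 1e-12)

    def test_normalization_bounds(self, rng):
        for _ in range(10):
            g = random_binary_graph(rng, 8)
            cc, _ = clustering_coefficient(g)
            el, _ = local_efficiency(g)
            partition, _ = detect_modules(g, seed=1)
            p = participation_coefficient(g, partition)
            d = shortest_path_lengths(g)
            for v in (cc, el, p):
                assert np.all((v >= -1e-12) & (v <= 1 + 1e-12))
            assert 0 <= global_efficiency(d) <= 1


class TestPlantedStateOrdering:
    def test_degree_declines_from_highest_to_lowest_mean_state(self):
        """At a fixed 0.3 threshold, states with lower mean FC keep fewer edges."""
        from dfcstates.synth import even_partition, make_state_covariances
        from dfcstates.windows import fisher_z

        covs = make_state_covariances(
            30, 4, (0.58, 0.39, 0.25, 0.20), even_partition(30, 5)
        )
        mean_degrees = []
        for c in covs:
            z = fisher_z(c.correlation)
            g = threshold_state(z, tau=0.3, mode="binary")
            mean_degrees.append(degree(g).mean())
        assert np.all(np.diff(mean_degrees) <= 1e-12)
        assert mean_degrees[0] > mean_degrees[-1]


class TestStateMetrics:
    def test_tables_complete(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 0.8, (10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        nodes, glob = state_metrics(m, tau=0.3, seed=0)
        assert len(nodes) == 10
        assert {"degree", "participation", "within_module_z"} <= set(nodes.columns)
        assert 0 <= glob["sparsity"] <= 1
        assert glob["global_efficiency"] <= 1
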