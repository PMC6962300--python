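"""Topology, node strengths and the truncated power-law fit."""

import itertools

import numpy as np
import pytest
from scipy import stats

from connectoflux.matrices import ThresholdSpec, apply_threshold
from connectoflux.structure import (
    ClusteringSeries,
    clustering_coefficient,
    clustering_differences,
    fit_strength_model,
    ks_distance,
    largest_component_fraction,
    node_strengths,
    truncated_power_cdf,
)
from connectoflux.synthetic import sample_strengths

from conftest import net_with_explicit_threshold, random_symmetric


def adjacency_net(edges, n):
    w = np.zeros((n, n))
    for a, b in edges:
        w[a, b] = w[b, a] = 1.0
    return net_with_explicit_threshold(w, w_t=0.5)


def lcc_oracle(edges, n):
    """Breadth-first component search, independent of scipy/networkx."""
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, best = set(), 0
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        best = max(best, len(comp))
    return best / n


def transitivity_oracle(adj):
    """3 * triangles / connected triples by explicit enumeration."""
    n = adj.shape[0]
    triangles = sum(
        adj[i, j] and adj[j, k] and adj[i, k]
        for i, j, k in itertools.combinations(range(n), 3)
    )
    triples = sum(
        int(adj[i, j] and adj[j, k])
        for j in range(n)
        for i, k in itertools.combinations(
            [v for v in range(n) if v != j], 2
        )
    )
    return 3 * triangles / triples if triples else 0.0


class TestLargestComponent:
    def test_complete_graph(self):
        net = adjacency_net(itertools.combinations(range(5), 2), 5)
        assert largest_component_fraction(net) == 1.0

    def test_all_singletons(self):
        net = adjacency_net([], 5)
        assert largest_component_fraction(net) == pytest.approx(0.2)

    def test_two_disjoint_triangles(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        net = adjacency_net(edges, 6)
        assert largest_component_fraction(net) == pytest.approx(0.5)

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            possible = list(itertools.combinations(range(n), 2))
            k = int(rng.integers(0, len(possible) + 1))
            idx = rng.choice(len(possible), size=k, replace=False)
            edges = [possible[i] for i in idx]
            net = adjacency_net(edges, n)
            assert largest_component_fraction(net) == pytest.approx(
                lcc_oracle(edges, n)
            )

    def test_monotone_in_threshold(self, rng):
        m = random_symmetric(40, rng)
        fracs = [
            largest_component_fraction(
                apply_threshold(m, ThresholdSpec(0.0, float(t), 0.0))
            )
            for t in np.linspace(0, 1, 11)
        ]
        assert all(b <= a for a, b in zip(fracs, fracs[1:]))


class TestClustering:
    def test_single_triangle(self):
        net = adjacency_net([(0, 1), (1, 2), (0, 2)], 3)
        assert clustering_coefficient(net) == 1.0

    def test_star_graph(self):
        net = adjacency_net([(0, i) for i in range(1, 5)], 5)
        assert clustering_coefficient(net) == 0.0

    def test_triangle_with_pendant(self):
        net = adjacency_net([(0, 1), (1, 2), (0, 2), (2, 3)], 4)
        assert clustering_coefficient(net) == pytest.approx(0.6)

    def test_exhaustive_small_graphs(self):
        # every graph on 4 nodes
        pairs = list(itertools.combinations(range(4), 2))
        for bits in range(2 ** len(pairs)):
            edges = [e for k, e in enumerate(pairs) if bits >> k & 1]
            net = adjacency_net(edges, 4)
            assert clustering_coefficient(net) == pytest.approx(
                transitivity_oracle(net.adjacency)
            )

    def test_random_graphs_up_to_seven_nodes(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 8))
            possible = list(itertools.combinations(range(n), 2))
            k = int(rng.integers(0, len(possible) + 1))
            idx = rng.choice(len(possible), size=k, replace=False)
            net = adjacency_net([possible[i] for i in idx], n)
            assert clustering_coefficient(net) == pytest.approx(
                transitivity_oracle(net.adjacency)
            )

    def test_igraph_cross_check(self, rng):
        igraph = pytest.importorskip("igraph")
        m = random_symmetric(30, rng)
        net = apply_threshold(m, ThresholdSpec(0.0, 0.5, 0.0))
        g = igraph.Graph.Adjacency(
            net.adjacency.astype(int).tolist(), mode="undirected"
        )
        assert clustering_coefficient(net) == pytest.approx(
            g.transitivity_undirected(mode="zero")
        )


class TestClusteringDifferences:
    def test_flat_series(self):
        s = ClusteringSeries(np.array([0.0, 0.5, 1.0]), np.array([0.4, 0.4, 0.4]))
        np.testing.assert_allclose(clustering_differences(s), [0.0, 0.0])

    def test_direct_subtraction(self):
        s = ClusteringSeries(np.array([0.0, 1.0, 2.0]), np.array([0.5, 0.3, 0.3]))
        np.testing.assert_allclose(clustering_differences(s), [0.2, 0.0])

    def test_shape_contract(self):
        t = np.linspace(-2, 2, 9)
        s = ClusteringSeries(t, np.linspace(1, 0, 9))
        assert clustering_differences(s).size == 8

    def test_too_short(self):
        with pytest.raises(ValueError):
            clustering_differences(
                ClusteringSeries(np.array([0.0]), np.array([0.5]))
            )

    def test_non_ascending_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClusteringSeries(np.array([1.0, 0.0]), np.array([0.1, 0.2]))


class TestNodeStrengths:
    def test_empty_network(self):
        net = net_with_explicit_threshold(np.zeros((4, 4)), w_t=0.1)
        assert np.all(node_strengths(net) == 0.0)

    def test_perfect_matching_unit_weights(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = -1.0
        net = net_with_explicit_threshold(w, w_t=0.5)
        np.testing.assert_allclose(node_strengths(net), np.ones(4))

    def test_row_sum_oracle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.6
        w[0, 2] = w[2, 0] = -0.5
        w[1, 2] = w[2, 1] = 0.3
        net = net_with_explicit_threshold(w, w_t=0.0)
        np.testing.assert_allclose(node_strengths(net), [1.1, 0.9, 0.8])


class TestKSDistance:
    def test_two_point_hand_evaluation(self):
        # model quantiles at probabilities 0.25 and 0.75 against a 2-point
        # empirical CDF: every gap is exactly 0.25
        sample = np.array([0.25, 0.75])
        assert ks_distance(sample, lambda x: x) == pytest.approx(0.25)

    def test_midpoint_match_best_case(self):
        n = 10
        sample = (np.arange(n) + 0.5) / n  # F(x) = x hits every step midpoint
        assert ks_distance(sample, lambda x: x) <= 1 / (2 * n) + 1e-12

    def test_disjoint_support(self):
        sample = np.array([-5.0, -4.0, -3.0])
        assert ks_distance(sample, lambda x: np.clip(x, 0, 1)) == 1.0

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            ks_distance(np.array([2.0, 1.0]), lambda x: x)

    def test_matches_scipy_kstest(self, rng):
        x = np.sort(rng.normal(size=200))
        ours = ks_distance(x, stats.norm.cdf)
        assert ours == pytest.approx(stats.kstest(x, stats.norm.cdf).statistic)


class TestFitStrengthModel:
    def test_uniform_special_case_recovery(self):
        x = sample_strengths(gamma=0.0, ns_max=3.0, ns_min=1.0, n=10_000, seed=2)
        fit = fit_strength_model(x)
        assert -0.1 <= fit.gamma <= 0.1
        assert fit.ks_D < 0.02

    def test_gamma_two_recovery(self):
        x = sample_strengths(gamma=2.0, ns_max=5.0, ns_min=0.0, n=10_000, seed=3)
        fit = fit_strength_model(x)
        assert 1.8 <= fit.gamma <= 2.2

    def test_self_consistency_on_exact_quantiles(self):
        gamma, ns_max, ns_min, n = 1.5, 4.0, 1.0, 200
        probs = (np.arange(n) + 0.5) / n
        # invert the model CDF exactly
        u = (ns_max - ns_min) * (1 - probs) ** (1 / (gamma + 1))
        sample = np.sort(ns_max - u)
        d = ks_distance(
            sample, lambda v: truncated_power_cdf(v, gamma, ns_max, ns_min)
        )
        assert d <= 1 / n

    def test_model_beats_normal_for_skewed_gamma(self):
        for gamma, seed in [(1.0, 4), (2.0, 5), (4.0, 6)]:
            x = sample_strengths(gamma, ns_max=6.0, ns_min=0.0, n=5000, seed=seed)
            fit = fit_strength_model(x)
            assert fit.ks_D < fit.ks_D_normal

    def test_ns_max_exceeds_observed_max(self):
        x = sample_strengths(1.0, 5.0, 0.0, 1000, seed=7)
        fit = fit_strength_model(x)
        assert fit.ns_max > x.max()

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_strength_model(np.full(20, 1.0))
        with pytest.raises(ValueError):
            fit_strength_model(np.arange(5, dtype=float))
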