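import math

import numpy as np
import pytest

import bionet as bn
from bionet.proximity import SizeError, rw_solver

from conftest import random_weighted_graph


class TestBestPath:
    def test_single_edge(self, plain_graph_factory):
        wg = plain_graph_factory([("s", "t", 0.6)])
        assert bn.best_path_probability(wg, "s", "t") == pytest.approx(0.6)

    def test_direct_beats_two_hop(self, three_edge_graph):
        # max(0.5 direct, 0.25 via a)
        assert bn.best_path_probability(three_edge_graph, "s", "t") == pytest.approx(0.5)

    def test_disconnected_zero_and_self_one(self, plain_graph_factory):
        wg = plain_graph_factory([("s", "a", 0.5), ("t", "b", 0.5)])
        assert bn.best_path_probability(wg, "s", "t") == 0.0
        assert bn.best_path_probability(wg, "s", "s") == 1.0

    def test_matches_exhaustive_enumeration(self):
        """Dijkstra on -log weights equals brute-force simple-path search."""
        import networkx as nx

        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(n - 1, min(n * (n - 1) // 2, 12) + 1))
            wg = random_weighted_graph(rng, n, m)
            G = nx.Graph()
            G.add_nodes_from(wg.graph.node_ids)
            for e in wg.graph.edges():
                G.add_edge(e.source, e.target, w=wg.w(e))
            s, t = "n00", "n01"
            best = 0.0
            for path in nx.all_simple_paths(G, s, t):
                pr = math.prod(G[u][v]["w"] for u, v in zip(path, path[1:]))
                best = max(best, pr)
            assert bn.best_path_probability(wg, s, t) == pytest.approx(best, abs=1e-12)


class TestRealizationSampling:
    def test_weight_one_keeps_all_and_zero_drops_all(self, plain_graph_factory):
        wg1 = plain_graph_factory([("a", "b"), ("b", "c")])
        rng = np.random.default_rng(0)
        assert len(bn.sample_realization(wg1, rng)) == 2
        wg0 = bn.WeightedGraph(wg1.graph, {e: 0.0 for e in wg1.graph.edges()})
        assert bn.sample_realization(wg0, rng) == []

    def test_inclusion_frequency_binomial(self, plain_graph_factory):
        wg = plain_graph_factory([("a", "b", 0.5)])
        rng = np.random.default_rng(7)
        hits = sum(len(bn.sample_realization(wg, rng)) for _ in range(10_000))
        se = math.sqrt(0.25 / 10_000)
        assert abs(hits / 10_000 - 0.5) < 3 * se

    def test_uncapped_weight_rejected(self, plain_graph_factory):
        wg = plain_graph_factory([("a", "b")])
        wg.weight[next(iter(wg.graph.edges()))] = 1.5
        with pytest.raises(ValueError):
            bn.sample_realization(wg, np.random.default_rng(0))


class TestReliabilityAndErd:
    def test_worked_example_oracle(self, three_edge_graph):
        rel, erd = bn.exact_reliability_oracle(three_edge_graph, "s", "t")
        assert rel == pytest.approx(0.625, abs=1e-12)
        assert erd == pytest.approx(1.2, abs=1e-12)

    def test_chain_oracle(self, plain_graph_factory):
        wg = plain_graph_factory([("s", "a", 0.5), ("a", "t", 0.5)])
        rel, erd = bn.exact_reliability_oracle(wg, "s", "t")
        assert rel == pytest.approx(0.25)
        assert erd == pytest.approx(2.0)

    def test_single_edge_oracle(self, plain_graph_factory):
        wg = plain_graph_factory([("s", "t", 0.9)])
        assert bn.exact_reliability_oracle(wg, "s", "t") == (
            pytest.approx(0.9),
            pytest.approx(1.0),
        )

    def test_oracle_size_limit(self):
        rng = np.random.default_rng(0)
        wg = random_weighted_graph(rng, 12, 25)
        with pytest.raises(SizeError):
            bn.exact_reliability_oracle(wg, "n00", "n01")

    def test_mc_matches_oracle_on_worked_example(self, three_edge_graph):
        params = bn.ProximityParams(measure="reliability", n_samples=20_000, seed=3)
        est = bn.network_reliability(three_edge_graph, "s", "t", params)
        assert abs(est.value - 0.625) < 4 * est.std_error
        erd = bn.expected_reliable_distance(three_edge_graph, "s", "t", params)
        assert erd.value == pytest.approx(1.2, abs=0.05)

    def test_certain_and_disconnected_exact(self, plain_graph_factory):
        wg = plain_graph_factory([("s", "t", 1.0)])
        params = bn.ProximityParams(measure="reliability", n_samples=100, seed=0)
        assert bn.network_reliability(wg, "s", "t", params).value == 1.0
        wg2 = plain_graph_factory([("s", "a", 0.5), ("t", "b", 0.5)])
        assert bn.network_reliability(wg2, "s", "t", params).value == 0.0

    def test_erd_conditioning_single_edge(self, plain_graph_factory):
        """Conditioned on connection, a single 0.3 edge always has distance 1."""
        wg = plain_graph_factory([("s", "t", 0.3)])
        params = bn.ProximityParams(measure="expected_reliable_distance",
                                    n_samples=500, seed=1)
        assert bn.expected_reliable_distance(wg, "s", "t", params).value == 1.0

    def test_erd_undefined_when_never_connected(self, plain_graph_factory):
        wg = plain_graph_factory([("s", "t")])
        wg.weight[next(iter(wg.graph.edges()))] = 0.0
        params = bn.ProximityParams(measure="expected_reliable_distance",
                                    n_samples=100, seed=0)
        est = bn.expected_reliable_distance(wg, "s", "t", params)
        assert not est.defined

    def test_degenerate_all_weights_one(self):
        """Reliability 1 and ERD = unweighted shortest path when edges are sure."""
        rng = np.random.default_rng(5)
        wg = random_weighted_graph(rng, 7, 10, wmin=1.0, wmax=1.0)
        import networkx as nx

        G = nx.Graph((e.source, e.target) for e in wg.graph.edges())
        params = bn.ProximityParams(measure="reliability", n_samples=50, seed=0)
        for t in ("n01", "n03"):
            if not nx.has_path(G, "n00", t):
                continue
            assert bn.network_reliability(wg, "n00", t, params).value == 1.0
            erd = bn.expected_reliable_distance(wg, "n00", t, params)
            assert erd.value == nx.shortest_path_length(G, "n00", t)

    def test_mc_within_four_se_of_oracle(self):
        """Seeded MC estimates stay within 4 SE of exhaustive enumeration."""
        rng = np.random.default_rng(2024)
        bad = 0
        for trial in range(50):
            n = int(rng.integers(4, 8))
            m = int(rng.integers(3, 11))
            wg = random_weighted_graph(rng, n, m)
            rel, erd = bn.exact_reliability_oracle(wg, "n00", "n01")
            params = bn.ProximityParams(measure="reliability", n_samples=20_000,
                                        seed=trial)
            est = bn.network_reliability(wg, "n00", "n01", params)
            se = max(est.std_error, 1e-9)
            if abs(est.value - rel) > 4 * se:
                bad += 1
        assert bad == 0

    def test_monotone_in_edge_weight(self, plain_graph_factory):
        """Raising any edge weight never lowers exact reliability."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            wg = random_weighted_graph(rng, 5, 6)
            rel, _ = bn.exact_reliability_oracle(wg, "n00", "n01")
            e = list(wg.graph.edges())[int(rng.integers(6))]
            wg.weight[e] = min(1.0, wg.weight[e] + 0.2)
            rel2, _ = bn.exact_reliability_oracle(wg, "n00", "n01")
            assert rel2 >= rel - 1e-12

    def test_best_path_lower_bounds_reliability(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            wg = random_weighted_graph(rng, 6, 8)
            pbp = bn.best_path_probability(wg, "n00", "n01")
            rel, _ = bn.exact_reliability_oracle(wg, "n00", "n01")
            assert pbp <= rel + 1e-12

    def test_bounded_neighborhood_estimate(self, default_sim):
        """Bounding to a neighborhood subgraph keeps the estimate finite & sane."""
        graph, truth = default_sim
        wg = bn.apply_weights(graph, bn.WeightingConfig(cap=True))
        s, t = truth.future_links[0]
        params = bn.ProximityParams(measure="reliability", n_samples=300,
                                    seed=0, bounding=(120, 3))
        est = bn.network_reliability(wg, s, t, params)
        assert 0.0 <= est.value <= 1.0


class TestRandomWalk:
    def test_two_node_closed_form(self, plain_graph_factory):
        """One edge, beta=0.2: stationary system gives d'(s,t)=4/9."""
        wg = plain_graph_factory([("s", "t")], cap=False)
        est = bn.random_walk_proximity(wg, "s", "t", bn.ProximityParams(beta=0.2))
        assert est.value == pytest.approx(4 / 9, abs=1e-9)

    def test_self_proximity(self, plain_graph_factory):
        wg = plain_graph_factory([("s", "t")], cap=False)
        est = bn.random_walk_proximity(wg, "s", "s", bn.ProximityParams(beta=0.2))
        assert est.value == pytest.approx(5 / 9, abs=1e-9)

    def test_stationary_sums_to_one(self):
        rng = np.random.default_rng(1)
        wg = random_weighted_graph(rng, 20, 40, cap=False)
        solver = rw_solver(wg, 0.2)
        for s in ("n00", "n07", "n19"):
            assert solver.stationary(s).sum() == pytest.approx(1.0, abs=1e-9)

    def test_dangling_root_is_point_mass(self, plain_graph_factory):
        wg = plain_graph_factory([("a", "b")], cap=False)
        wg.graph.add_node("iso", "N")
        est = bn.random_walk_proximity(wg, "iso", "a", bn.ProximityParams())
        # d'(iso,a)=0 and d'(a,iso)=0, so the symmetric average is 0
        assert est.value == 0.0
        self_est = bn.random_walk_proximity(wg, "iso", "iso", bn.ProximityParams())
        assert self_est.value == 1.0

    def test_simulation_agrees_with_exact(self):
        """10^6-step simulated visit frequency within 0.01 of the solve."""
        rng = np.random.default_rng(14)
        wg = random_weighted_graph(rng, 20, 40, cap=False)
        exact = bn.random_walk_proximity(wg, "n00", "n05", bn.ProximityParams())
        sim = bn.random_walk_proximity(
            wg, "n00", "n05",
            bn.ProximityParams(rw_method="simulate", rw_iterations=1_000_000, seed=0),
        )
        assert abs(exact.value - sim.value) < 0.01

    def test_uncapped_weights_allowed(self, plain_graph_factory):
        wg = plain_graph_factory([("s", "t"), ("t", "u")], cap=False)
        for e in wg.graph.edges():
            wg.weight[e] = 3.0
        est = bn.random_walk_proximity(wg, "s", "u", bn.ProximityParams())
        assert 0.0 < est.value < 1.0


class TestProximityMatrix:
    def test_two_node_best_path(self, plain_graph_factory):
        wg = plain_graph_factory([("a", "b", 0.6)])
        M = bn.proximity_matrix(wg, ["a", "b"], bn.ProximityParams(measure="best_path"))
        assert M == pytest.approx(np.array([[1.0, 0.6], [0.6, 1.0]]))

    def test_symmetry(self, default_sim_rw):
        wg, truth = default_sim_rw
        nodes = sorted(truth.families[0])[:6]
        M = bn.proximity_matrix(wg, nodes, bn.ProximityParams())
        assert np.allclose(M, M.T)

    def test_reliability_chain_matches_oracle(self, plain_graph_factory):
        wg = plain_graph_factory([("a", "b", 0.8), ("b", "c", 0.8)])
        params = bn.ProximityParams(measure="reliability", n_samples=20_000, seed=9)
        M = bn.proximity_matrix(wg, ["a", "b", "c"], params)
        rel, _ = bn.exact_reliability_oracle(wg, "a", "c")
        assert M[0, 2] == pytest.approx(rel, abs=0.02)
        assert np.allclose(np.diag(M), 1.0)

    def test_rw_matrix_matches_pairwise_calls(self, plain_graph_factory):
        wg = plain_graph_factory([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")],
                                 cap=False)
        nodes = ["a", "b", "c", "d"]
        M = bn.proximity_matrix(wg, nodes, bn.ProximityParams())
        for i, s in enumerate(nodes):
            for j, t in enumerate(nodes):
                est = bn.random_walk_proximity(wg, s, t, bn.ProximityParams())
                assert M[i, j] == pytest.approx(est.value, abs=1e-10)
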