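"""Hub correction, RWR propagation, the degree-preserving null and subnetworks."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ednet.propagation import (
    clustering_coefficient,
    configuration_null,
    empirical_pvalues,
    extract_subnetwork,
    hub_correct,
    propagate_with_null,
    randomize_degree_preserving,
    rwr,
)


def weighted(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


def rwr_linear_solve(g, seeds, restart):
    """Oracle: direct solution of s = (1-a) W s + a e."""
    nodes = list(g)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    deg = a.sum(axis=0)
    w = a / np.where(deg == 0, 1.0, deg)
    e = np.array([seeds.get(n, 0.0) for n in nodes], dtype=float)
    e /= e.sum()
    s = np.linalg.solve(np.eye(len(nodes)) - (1 - restart) * w, restart * e)
    return pd.Series(s, index=nodes)


class TestHubCorrect:
    def test_single_edge_identity(self):
        g = hub_correct(weighted([("a", "b", 1.0)]))
        assert g["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_three_leaf_star(self):
        g = weighted([("c", "x", 1.0), ("c", "y", 1.0), ("c", "z", 1.0)])
        out = hub_correct(g, gamma=0.5)
        for leaf in "xyz":
            assert out["c"][leaf]["weight"] == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_gamma_zero_unchanged(self):
        g = weighted([("a", "b", 0.3), ("b", "c", 0.7)])
        out = hub_correct(g, gamma=0.0)
        assert out["a"]["b"]["weight"] == pytest.approx(0.3)
        assert out["b"]["c"]["weight"] == pytest.approx(0.7)

    def test_uses_input_degrees_not_iterative(self):
        # star with unequal weights: every corrected edge divides by the
        # same original centre degree
        g = weighted([("c", "x", 0.5), ("c", "y", 1.0)])
        out = hub_correct(g, gamma=1.0)
        assert out["c"]["x"]["weight"] == pytest.approx(0.5 / (1.5 * 0.5))
        assert out["c"]["y"]["weight"] == pytest.approx(1.0 / (1.5 * 1.0))


class TestRwr:
    def test_single_node_conservation(self):
        g = nx.Graph()
        g.add_node("a")
        s = rwr(g, {"a": 1.0}, restart=0.3)
        assert s["a"] == pytest.approx(1.0)

    def test_two_node_closed_form(self):
        s = rwr(weighted([("A", "B", 1.0)]), {"A": 1.0}, restart=0.5)
        assert s["A"] == pytest.approx(2 / 3, abs=1e-12)
        assert s["B"] == pytest.approx(1 / 3, abs=1e-12)

    def test_scores_sum_to_one(self):
        g = nx.barabasi_albert_graph(50, 2, seed=1)
        nx.set_edge_attributes(g, 1.0, "weight")
        s = rwr(g, {0: 1.0, 5: 2.0})
        assert s.sum() == pytest.approx(1.0, abs=1e-10)

    def test_symmetry_under_automorphism(self):
        g = nx.cycle_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        s = rwr(g, {0: 1.0})
        assert s[1] == pytest.approx(s[5], abs=1e-10)
        assert s[2] == pytest.approx(s[4], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_system_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(60, 0.08, seed=seed)
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        seeds = {int(n): float(rng.uniform(0.5, 2.0)) for n in rng.choice(60, 5, replace=False)}
        mine = rwr(g, seeds, restart=0.15)
        oracle = rwr_linear_solve(g, seeds, restart=0.15)
        assert float(np.abs(mine - oracle).max()) < 1e-10

    def test_matches_igraph_personalized_pagerank(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(2)
        g = nx.connected_watts_strogatz_graph(40, 4, 0.3, seed=2)
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
        seeds = {0: 1.0, 7: 2.0, 13: 0.5}
        mine = rwr(g, seeds, restart=0.15)
        nodes = list(g)
        ig = igraph.Graph([(nodes.index(u), nodes.index(v)) for u, v in g.edges()])
        weights = [g[u][v]["weight"] for u, v in g.edges()]
        reset = [seeds.get(n, 0.0) for n in nodes]
        ref = ig.personalized_pagerank(damping=0.85, reset=reset, weights=weights)
        assert np.abs(mine.to_numpy() - np.array(ref)).max() < 1e-8

    def test_raising_seed_importance_raises_own_score(self):
        g = nx.path_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        low = rwr(g, {0: 1.0, 5: 1.0})
        high = rwr(g, {0: 3.0, 5: 1.0})
        assert high[0] > low[0]

    def test_no_seed_in_network_error(self):
        g = weighted([("a", "b", 1.0)])
        with pytest.raises(ValueError):
            rwr(g, {"zzz": 1.0})


class TestConfigurationNull:
    def test_degree_sequence_preserved(self):
        g = nx.barabasi_albert_graph(60, 2, seed=0)
        rng = np.random.default_rng(1)
        for _ in range(10):
            h = randomize_degree_preserving(g, rng)
            assert sorted(d for _, d in h.degree()) == sorted(d for _, d in g.degree())
            assert set(h) == set(g)

    def test_triangle_forced_isomorphic(self):
        g = nx.cycle_graph(3)
        rng = np.random.default_rng(0)
        h = randomize_degree_preserving(g, rng)
        assert sorted(map(tuple, map(sorted, h.edges()))) == sorted(
            map(tuple, map(sorted, g.edges()))
        )

    def test_randomization_mixes(self):
        g = nx.barabasi_albert_graph(200, 2, seed=3)
        rng = np.random.default_rng(4)
        orig = {frozenset(e) for e in g.edges()}
        overlaps = []
        for _ in range(10):
            h = randomize_degree_preserving(g, rng)
            shared = len(orig & {frozenset(e) for e in h.edges()})
            overlaps.append(shared / g.number_of_edges())
        assert np.mean(overlaps) < 0.5

    def test_null_scores_shape_and_star_fallback(self):
        g = nx.star_graph(5)  # swaps impossible; exercises stub-matching fallback
        nx.set_edge_attributes(g, 0.5, "weight")
        scores = configuration_null(g, {1: 1.0}, n_random=5, seed=0)
        assert scores.shape == (6, 5)
        assert np.allclose(scores.sum(axis=0), 1.0)


class TestEmpiricalPvalues:
    def test_formula(self):
        emp = pd.Series({"a": 1.0, "b": 0.0, "c": 0.5})
        rng = np.random.default_rng(0)
        null = pd.DataFrame(rng.uniform(0.4, 0.6, size=(3, 1000)),
                            index=["a", "b", "c"])
        null.loc["c"] = np.concatenate([np.full(900, 0.4), np.full(100, 0.6)])
        p = empirical_pvalues(emp, null)
        assert p["a"] == 0.0  # exceeds all
        assert p["b"] == 1.0  # exceeds none
        assert p["c"] == pytest.approx(0.1)  # exceeds 900 of 1000

    def test_ties_count_against(self):
        emp = pd.Series({"a": 0.5})
        null = pd.DataFrame([[0.5, 0.4]], index=["a"])
        assert empirical_pvalues(emp, null)["a"] == pytest.approx(0.5)

    def test_missing_node_scored_zero(self):
        emp = pd.Series({"a": 0.1, "b": 0.1})
        null = pd.DataFrame([[0.05, 0.2]], index=["a"])
        p = empirical_pvalues(emp, null)
        assert p["b"] == 0.0  # absent from null -> treated as 0 there


class TestSubnetwork:
    def test_all_insignificant_empty(self):
        g = nx.path_graph(4)
        p = pd.Series(1.0, index=list(g))
        assert extract_subnetwork(g, p).number_of_nodes() == 0

    def test_isolated_significant_node_discarded(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        p = pd.Series({"a": 0.001, "b": 0.001, "c": 0.001, "d": 0.5})
        sub = extract_subnetwork(g, p)
        assert set(sub) == {"a", "b"}
        assert sub.number_of_edges() == 1

    def test_clustering_examples(self):
        assert clustering_coefficient(nx.complete_graph(3)) == pytest.approx(1.0)
        assert clustering_coefficient(nx.path_graph(3)) == pytest.approx(0.0)
        assert clustering_coefficient(nx.path_graph(3), "transitivity") == pytest.approx(0.0)

    def test_propagate_with_null_planted_module(self):
        from ednet.synthetic import SyntheticNetworkSpec, gen_network

        spec = SyntheticNetworkSpec(
            n_nodes=80, attachment_parameter=2, planted_module_density=1.0, seed=0
        )
        module = spec.node_names()[40:50]
        spec.planted_module_nodes = module
        g, _ = gen_network(spec)
        res, sub = propagate_with_null(g, {m: 1.0 for m in module[:5]}, n_random=50, seed=0)
        assert res["score"].sum() == pytest.approx(1.0, abs=1e-9)
        assert res.loc[module, "pvalue"].mean() < res["pvalue"].mean()
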