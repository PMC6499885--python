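"""Subnetwork expansion and Monte Carlo specificity testing."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nephrosig.network import (
    Interactome,
    component_metrics,
    expand_subnetwork,
    monte_carlo_null,
)
from nephrosig.synthetic import ScenarioConfig, gen_interactome


def make_graph(edges):
    return Interactome(
        pd.DataFrame(edges, columns=["node_a", "node_b", "evidence"])
    )


def expand_oracle(g: Interactome, seeds, min_evidence):
    """Brute-force networkx reimplementation of the expansion rule."""
    gx = g.to_networkx(min_evidence=min_evidence)
    seeds = [s for s in seeds if s in gx]
    inters = set()
    for n in gx.nodes:
        if n in seeds:
            continue
        if sum(1 for s in seeds if gx.has_edge(n, s)) >= 2:
            inters.add(n)
    sub = gx.subgraph(set(seeds) | inters)
    comps = list(nx.connected_components(sub)) if sub.number_of_nodes() else []
    big = max(comps, key=len) if comps else set()
    lc = sub.subgraph(big)
    return {
        "intermediates": inters,
        "n_nodes": sub.number_of_nodes(),
        "n_edges": sub.number_of_edges(),
        "largest_component_node_count": lc.number_of_nodes(),
        "largest_component_edge_count": lc.number_of_edges(),
    }


class TestExpandSubnetwork:
    def test_hand_enumerated_example(self):
        g = make_graph(
            [("A", "X", 2), ("B", "X", 3), ("C", "Y", 2), ("A", "B", 2)]
        )
        sub = expand_subnetwork(g, ["A", "B", "C"], min_evidence=2)
        assert sub.intermediate_nodes == ["X"]  # Y touches only one seed
        assert sub.metrics["largest_component_node_count"] == 3
        assert sub.metrics["largest_component_edge_count"] == 3

    def test_seed_clique_gains_no_intermediates(self):
        g = make_graph(
            [("A", "B", 5), ("B", "C", 5), ("A", "C", 5), ("C", "Z", 5)]
        )
        sub = expand_subnetwork(g, ["A", "B", "C"])
        assert sub.intermediate_nodes == []
        assert sub.metrics["n_edges"] == 3

    def test_threshold_above_all_evidence_gives_edgeless_result(self):
        g = make_graph([("A", "B", 1), ("B", "C", 1)])
        sub = expand_subnetwork(g, ["A", "B"], min_evidence=5)
        assert sub.metrics["n_edges"] == 0
        assert sub.metrics["largest_component_node_count"] == 1

    def test_empty_and_missing_seeds(self):
        g = make_graph([("A", "B", 2)])
        with pytest.raises(ValueError, match="empty"):
            expand_subnetwork(g, [])
        sub = expand_subnetwork(g, ["A", "B", "Q"])
        assert sub.missing_seeds == ["Q"]

    def test_evidence_aggregation_and_self_loop_rejection(self):
        g = make_graph([("A", "B", 1), ("B", "A", 1)])
        assert g.edges["evidence"].tolist() == [2]
        with pytest.raises(ValueError, match="self-loops"):
            make_graph([("A", "A", 1)])

    def test_matches_networkx_oracle_on_random_graphs(self, rng):
        for trial in range(10):
            n = 40
            gnx = nx.gnp_random_graph(n, 0.12, seed=int(rng.integers(1e6)))
            edges = [
                (f"n{a}", f"n{b}", int(rng.integers(1, 4)))
                for a, b in gnx.edges
            ]
            if not edges:
                continue
            g = make_graph(edges)
            seeds = [f"n{i}" for i in rng.choice(n, size=8, replace=False)]
            for min_ev in (1, 2, 3):
                sub = expand_subnetwork(g, seeds, min_evidence=min_ev)
                ref = expand_oracle(g, seeds, min_ev)
                assert set(sub.intermediate_nodes) == ref["intermediates"]
                for key in (
                    "largest_component_node_count",
                    "largest_component_edge_count",
                ):
                    assert sub.metrics[key] == ref[key]

    def test_expansion_monotone_in_evidence_threshold(self, rng):
        edges = [
            (f"n{a}", f"n{b}", int(rng.integers(1, 5)))
            for a, b in nx.gnp_random_graph(50, 0.1, seed=7).edges
        ]
        g = make_graph(edges)
        seeds = [f"n{i}" for i in range(10) if f"n{i}" in g]
        prev_nodes, prev_edges = np.inf, np.inf
        for min_ev in (1, 2, 3, 4):
            sub = expand_subnetwork(g, seeds, min_evidence=min_ev)
            assert sub.metrics["n_nodes"] <= prev_nodes
            assert sub.metrics["n_edges"] <= prev_edges
            prev_nodes = sub.metrics["n_nodes"]
            prev_edges = sub.metrics["n_edges"]


class TestComponentMetrics:
    def test_triangle_and_path(self):
        tri = expand_subnetwork(
            make_graph([("A", "B", 9), ("B", "C", 9), ("A", "C", 9)]),
            ["A", "B", "C"],
        )
        m = component_metrics(tri)
        assert (m["n_nodes"], m["n_edges"], m["mean_degree"]) == (3, 3, 2.0)
        path = expand_subnetwork(
            make_graph([("A", "B", 9), ("B", "C", 9), ("C", "D", 9)]),
            ["A", "B", "C", "D"],
        )
        assert component_metrics(path)["mean_degree"] == pytest.approx(1.5)

    def test_agrees_with_fast_path_metrics(self, rng):
        edges = [
            (f"n{a}", f"n{b}", int(rng.integers(1, 4)))
            for a, b in nx.gnp_random_graph(60, 0.08, seed=11).edges
        ]
        g = make_graph(edges)
        seeds = [f"n{i}" for i in range(12) if f"n{i}" in g]
        sub = expand_subnetwork(g, seeds)
        slow = component_metrics(sub)
        for key, val in sub.metrics.items():
            assert slow[key] == val


class TestMonteCarloNull:
    def test_empirical_p_definition(self):
        g, seeds = gen_interactome(
            _small_cfg(planted_density=8.0, seed=3)
        )
        obs = expand_subnetwork(g, seeds)
        null = monte_carlo_null(
            g, g.nodes, k=len(seeds), observed=obs, n_iterations=99, seed=0
        )
        if (null.samples < null.observed).all():
            assert null.empirical_p == pytest.approx(0.01)
        assert null.empirical_p >= 1.0 / 100.0

    def test_too_few_iterations_rejected(self):
        g, seeds = gen_interactome(_small_cfg(seed=1))
        obs = expand_subnetwork(g, seeds)
        with pytest.raises(ValueError, match="resolution"):
            monte_carlo_null(g, g.nodes, 5, obs, n_iterations=10, seed=0)

    def test_planted_module_detected_null_seeds_not(self):
        cfg = _small_cfg(planted_density=6.0, seed=5)
        g, seeds = gen_interactome(cfg)
        obs = expand_subnetwork(g, seeds)
        null = monte_carlo_null(
            g, g.nodes, len(seeds), obs, n_iterations=200, seed=1
        )
        assert null.empirical_p <= 0.01
        # a random seed set of the same size is unremarkable
        rng = np.random.default_rng(2)
        rand_seeds = list(rng.choice(g.nodes, size=len(seeds), replace=False))
        obs_rand = expand_subnetwork(g, rand_seeds)
        null_rand = monte_carlo_null(
            g, g.nodes, len(seeds), obs_rand, n_iterations=200, seed=3
        )
        assert null_rand.empirical_p > 0.01

    def test_deterministic_given_seed(self):
        g, seeds = gen_interactome(_small_cfg(seed=8))
        obs = expand_subnetwork(g, seeds)
        a = monte_carlo_null(g, g.nodes, len(seeds), obs, 50, seed=4)
        b = monte_carlo_null(g, g.nodes, len(seeds), obs, 50, seed=4)
        assert np.array_equal(a.samples, b.samples)


def _small_cfg(planted_density=1.0, seed=0) -> ScenarioConfig:
    cfg = ScenarioConfig(rng_seed=seed)
    cfg.network.n_nodes = 300
    cfg.network.mean_degree = 8.0
    cfg.network.planted_seed_size = 25
    cfg.network.planted_density = planted_density
    return cfg
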