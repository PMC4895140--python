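"""Adoption-cascade decomposition vs hand computations and brute force."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from adoptspread import (
    Population,
    build_adoption_network,
    build_population,
    classify,
    component_stats,
    innovator_tree_correlation,
    max_relative_growth_rate,
    simulate,
    stable_subnetwork,
    vulnerable_forest,
)
from conftest import path_population, star_population


def random_toy(seed, n_max=50):
    """Random small substrate plus a random partial adoption log."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    p = rng.uniform(0.05, 0.3)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    pop = Population.from_edges(n, np.array(list(g.edges()), dtype=np.int64).reshape(-1, 2))
    adopters = rng.permutation(n)[: int(rng.integers(1, n + 1))]
    times = rng.integers(1, 8, size=len(adopters))
    log = pd.DataFrame({"node": adopters, "t": times}).sort_values(["t", "node"], ignore_index=True)
    return pop, log


class TestClassify:
    def test_triangle_sequence(self):
        pop = Population.from_edges(3, np.array([(0, 1), (1, 2), (0, 2)]))
        log = pd.DataFrame({"node": [0, 1, 2], "t": [1, 2, 3]})
        cls = classify(pop, log).set_index("node")
        assert cls.loc[0, "cls"] == "innovator"
        assert cls.loc[1, "cls"] == "vulnerable"
        assert cls.loc[2, "cls"] == "stable"

    def test_same_time_neighbours_exclude_each_other(self):
        pop = Population.from_edges(2, np.array([(0, 1)]))
        log = pd.DataFrame({"node": [0, 1], "t": [3, 3]})
        cls = classify(pop, log)
        assert (cls["phi_k"] == 0).all()
        assert (cls["cls"] == "innovator").all()

    def test_missing_node_raises_with_name(self):
        pop = Population.from_edges(3, np.array([(0, 1)]))
        log = pd.DataFrame({"node": [7], "t": [1]})
        with pytest.raises(ValueError, match="7"):
            classify(pop, log)

    def test_recovers_simulator_classes_without_collisions(self, deg_model, thr_model, rng):
        # generator oracle: the simulator's frozen-state counts equal the
        # strictly-earlier neighbour counts, so classification is exact
        pop = build_population(deg_model, thr_model, 3000, 0.4, rng)
        sim, log = simulate(pop, 0.002, 60, rng)
        cls = classify(pop, log).set_index("node")
        spont = sim.spontaneous
        social = cls.index[~spont[cls.index]]
        # social adopters crossed their threshold: phi_k >= ceil(k * phi)
        need = np.ceil(pop.degree[social] * pop.threshold[social] - 1e-9)
        assert (cls.loc[social, "phi_k"].to_numpy() >= need - 1e-9).all()


class TestAdoptionNetwork:
    def test_single_timestamp_gives_edgeless_network(self, small_population, rng):
        adopters = np.flatnonzero(~small_population.immune)[:50]
        log = pd.DataFrame({"node": adopters, "t": 1})
        net = build_adoption_network(small_population, log)
        assert net.n_edges == 0
        assert net.n_nodes == 50

    def test_sequential_chain_is_one_path(self):
        pop = path_population(6)
        log = pd.DataFrame({"node": np.arange(6), "t": np.arange(1, 7)})
        net = build_adoption_network(pop, log)
        stats = component_stats(net)
        assert stats.lc == 6 and stats.lc2 == 0

    def test_time_slicing_grows_monotonically(self):
        pop = path_population(6)
        log = pd.DataFrame({"node": np.arange(6), "t": np.arange(1, 7)})
        sizes = [build_adoption_network(pop, log, t).n_nodes for t in range(1, 7)]
        assert sizes == [1, 2, 3, 4, 5, 6]

    @pytest.mark.parametrize("seed", range(12))
    def test_components_match_networkx_oracle(self, seed):
        pop, log = random_toy(seed)
        net = build_adoption_network(pop, log)
        stats = component_stats(net, n_total=pop.n)
        # brute-force oracle: build the same graph in networkx and flood fill
        t_adopt = dict(zip(log["node"], log["t"]))
        g = nx.Graph()
        g.add_nodes_from(t_adopt)
        for u, v in pop.edges:
            if u in t_adopt and v in t_adopt and t_adopt[u] != t_adopt[v]:
                g.add_edge(u, v)
        ref = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        assert stats.lc == (ref[0] if ref else 0)
        assert stats.lc2 == (ref[1] if len(ref) > 1 else 0)
        assert sorted(stats.sizes, reverse=True) == ref

    @pytest.mark.parametrize("seed", range(12))
    def test_every_output_edge_in_substrate_and_time_distinct(self, seed):
        pop, log = random_toy(seed)
        substrate = {tuple(sorted(e)) for e in pop.edges}
        t_adopt = dict(zip(log["node"], log["t"]))
        for graph in (build_adoption_network(pop, log), stable_subnetwork(pop, log)):
            for u, v in graph.edges:
                assert tuple(sorted((u, v))) in substrate
                assert t_adopt[u] != t_adopt[v]


class TestStableSubnetwork:
    def test_empty_without_stable_adopters(self):
        pop = path_population(4)
        log = pd.DataFrame({"node": [0, 1], "t": [1, 2]})
        net = stable_subnetwork(pop, log)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_nodes_subset_of_adoption_network(self, small_population, rng):
        sim, log = simulate(small_population, 0.01, 40, rng)
        stab = stable_subnetwork(small_population, log)
        adopt = build_adoption_network(small_population, log)
        assert set(stab.nodes).issubset(set(adopt.nodes))


class TestVulnerableForest:
    def test_star_is_single_tree(self):
        k = 5
        pop = star_population(k)
        log = pd.DataFrame({"node": np.arange(k + 1), "t": [1] + [2] * k})
        trees, members = vulnerable_forest(pop, log)
        assert len(trees) == 1
        assert trees["s_v"].iloc[0] == k
        assert trees["depth"].iloc[0] == 1
        assert trees["root_cls"].iloc[0] == "innovator"

    def test_sequential_path_depth_equals_length(self):
        n = 7
        pop = path_population(n)
        log = pd.DataFrame({"node": np.arange(n), "t": np.arange(1, n + 1)})
        trees, members = vulnerable_forest(pop, log)
        assert len(trees) == 1
        assert trees["s_v"].iloc[0] == n - 1
        assert trees["depth"].iloc[0] == n - 1

    @pytest.mark.parametrize("seed", range(12))
    def test_forest_is_node_disjoint_and_time_increasing(self, seed):
        pop, log = random_toy(seed)
        trees, members = vulnerable_forest(pop, log)
        placed = members[members["root"] >= 0]
        # disjointness: one row per vulnerable node
        assert placed["node"].is_unique
        assert placed["node"].isin(log["node"]).all()
        # tree sizes add up
        assert trees["s_v"].sum() == len(placed)
        # time increases from root to member along the parent chain
        t_adopt = dict(zip(log["node"], log["t"]))
        for _, row in placed.iterrows():
            assert t_adopt[row["node"]] > t_adopt[row["root"]]

    def test_orphans_only_under_collisions(self, deg_model, thr_model, rng):
        pop = build_population(deg_model, thr_model, 2000, 0.3, rng)
        _, log = simulate(pop, 0.005, 50, rng)
        trees, members = vulnerable_forest(pop, log)
        # without injected collisions every vulnerable node has its unique
        # strictly-earlier neighbour, hence a tree
        assert (members["root"] >= 0).all()


class TestComponentStats:
    def test_two_cliques(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i, j) for i in range(5, 8) for j in range(i + 1, 8)]
        pop = Population.from_edges(8, np.array(edges))
        log = pd.DataFrame({"node": np.arange(8), "t": np.arange(1, 9)})
        stats = component_stats(build_adoption_network(pop, log))
        assert stats.lc == 5 and stats.lc2 == 3
        assert stats.sizes.sum() == 8

    def test_empty_graph(self):
        from adoptspread import Subgraph

        stats = component_stats(Subgraph(nodes=np.empty(0, dtype=np.int64), edges=np.empty((0, 2), dtype=np.int64)))
        assert stats.lc == 0 and stats.lc2 == 0


class TestTreeCorrelation:
    def test_all_trees_size_one_flat(self):
        trees = pd.DataFrame(
            {"root": [1, 2, 3], "s_v": [1, 1, 1], "depth": [1, 1, 1],
             "root_cls": ["innovator"] * 3, "root_degree": [2, 5, 5]}
        )
        table = innovator_tree_correlation(trees)
        assert (table["mean_s_v"] == 1).all()

    def test_matches_groupby_oracle(self, deg_model, thr_model, rng):
        pop = build_population(deg_model, thr_model, 4000, 0.3, rng)
        _, log = simulate(pop, 0.003, 60, rng)
        trees, _ = vulnerable_forest(pop, log)
        table = innovator_tree_correlation(trees)
        inn = trees[trees["root_cls"] == "innovator"]
        for _, row in table.iterrows():
            sel = inn[inn["root_degree"] == row["k"]]["s_v"]
            assert row["mean_s_v"] == pytest.approx(sel.mean())
            assert row["n_trees"] == len(sel)

    def test_stable_rooted_trees_excluded(self):
        trees = pd.DataFrame(
            {"root": [1, 2], "s_v": [1, 9], "depth": [1, 2],
             "root_cls": ["innovator", "stable"], "root_degree": [4, 4]}
        )
        table = innovator_tree_correlation(trees)
        assert table["mean_s_v"].iloc[0] == 1


class TestRGR:
    def test_instantaneous_cascade(self):
        log = pd.DataFrame({"node": np.arange(20), "t": np.full(20, 3)})
        assert max_relative_growth_rate(log) == 1.0

    def test_hand_computed_yearly_counts(self):
        # years: 2 + 8 + 10 adoptions out of 20 -> RGR = 0.5
        t = np.concatenate([np.full(2, 5), np.full(8, 18), np.full(10, 30)])
        log = pd.DataFrame({"node": np.arange(20), "t": t})
        assert max_relative_growth_rate(log) == 0.5

    def test_uniform_over_years(self):
        years = 5
        t = np.concatenate([np.full(6, 1 + 12 * y) for y in range(years)])
        log = pd.DataFrame({"node": np.arange(len(t)), "t": t})
        assert max_relative_growth_rate(log) == pytest.approx(1 / years)

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            max_relative_growth_rate(pd.DataFrame({"node": [], "t": []}))
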