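"""Network construction, betweenness centrality, link-partition statistics."""

import networkx as nx
import numpy as np
import pytest

from conftest import make_edges, make_network, make_truth, random_graph_network
from patternet.io import InteractionEdge
from patternet.network import (
    betweenness_centrality,
    brute_force_betweenness,
    build_network,
    count_links_by_group,
    expected_within_fraction,
    likelihood_score,
    permutation_null,
    within_fraction_per_gene,
)
from patternet.patterns import PatternGroup
from patternet.synth import generate_network

G2, G6 = PatternGroup.G2, PatternGroup.G6


class TestBuildNetwork:
    def test_induced_subgraph_drops_isolates_and_nonseeds(self):
        edges = make_edges([("A", "B"), ("B", "D")])
        net = build_network(edges, ["A", "B", "C"], {g: G2 for g in "ABC"})
        assert net.nodes == ["A", "B"]
        assert net.n_edges == 1

    def test_no_internal_edges_is_error(self):
        edges = make_edges([("X", "Y")])
        with pytest.raises(ValueError):
            build_network(edges, ["A", "B"], {"A": G2, "B": G2})

    def test_case_insensitive_matching(self):
        edges = [InteractionEdge("AKT1", "src", 700)]
        net = build_network(edges, ["Akt1", "Src"], {"Akt1": G2, "Src": G2})
        assert net.nodes == sorted(["Akt1", "Src"])

    def test_sbm_without_between_edges_components_match_modules(self):
        truth = make_truth({G2: 8, G6: 8})
        edges = generate_network(truth, p_in=0.9, p_out=0.0, p_decoy=0.0, seed=5)
        net = build_network(edges, truth.modules.keys(), truth.groups)
        comps = list(nx.connected_components(net.graph))
        modules = {
            frozenset(g for g in net.nodes if truth.modules[g] == m)
            for m in ("G2", "G6")
        }
        assert {frozenset(c) for c in comps} == modules


class TestBetweenness:
    def test_star_center(self):
        pairs = [("c", f"l{i}") for i in range(4)]
        net = make_network(pairs, {v: G2 for v in ["c", "l0", "l1", "l2", "l3"]})
        table = betweenness_centrality(net)
        assert table.at["c", "bc"] == pytest.approx(1.0)
        assert all(table.at[f"l{i}", "bc"] == 0.0 for i in range(4))
        assert table.at["c", "rank"] == 1

    def test_path_midpoint(self):
        net = make_network([("A", "B"), ("B", "C")], {v: G2 for v in "ABC"})
        assert betweenness_centrality(net).at["B", "bc"] == pytest.approx(1.0)

    def test_four_cycle_split_paths(self):
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
        net = make_network(pairs, {v: G2 for v in "abcd"})
        table = betweenness_centrality(net)
        # each opposite pair splits its two shortest paths 0.5/0.5
        assert np.allclose(table["bc"], 1 / 6)

    def test_two_disconnected_paths(self):
        pairs = [("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")]
        net = make_network(pairs, {v: G2 for v in "abcxyz"})
        table = betweenness_centrality(net)
        # midpoints carry 1 raw pair each; global normalization (6-1)(6-2)/2=10
        assert table.at["b", "bc"] == pytest.approx(0.1)
        assert table.at["y", "bc"] == pytest.approx(0.1)
        assert table.at["a", "bc"] == 0.0

    def test_small_graph_normalization_degenerate(self):
        net = make_network([("a", "b")], {"a": G2, "b": G2})
        assert (betweenness_centrality(net)["bc"] == 0).all()

    def test_matches_bruteforce_and_networkx(self):
        for seed in range(12):
            net = random_graph_network(8, 0.4, seed)
            if net is None:
                continue
            mine = betweenness_centrality(net)
            oracle = brute_force_betweenness(net)
            assert np.allclose(mine["bc"], oracle.loc[mine.index, "bc"], atol=1e-12)
            ref = nx.betweenness_centrality(net.graph, normalized=True)
            assert np.allclose(mine["bc"], [ref[v] for v in mine.index], atol=1e-12)

    def test_relabeling_invariance(self):
        net = random_graph_network(8, 0.4, 99)
        mapping = {v: f"z{i}" for i, v in enumerate(sorted(net.graph.nodes))}
        relabeled = build_network(
            [
                InteractionEdge(mapping[a], mapping[b], 700)
                for a, b in net.graph.edges
            ],
            mapping.values(),
            {m: G2 for m in mapping.values()},
        )
        t1 = betweenness_centrality(net)
        t2 = betweenness_centrality(relabeled)
        for v, m in mapping.items():
            assert t1.at[v, "bc"] == pytest.approx(t2.at[m, "bc"], abs=1e-14)

    def test_bruteforce_size_cap(self):
        net = random_graph_network(13, 0.5, 1)
        with pytest.raises(ValueError):
            brute_force_betweenness(net)

    def test_rank_tie_rule(self):
        # triangle plus pendant: a and b tie on bc; higher degree then id
        pairs = [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]
        net = make_network(pairs, {v: G2 for v in "abcd"})
        table = betweenness_centrality(net)
        assert list(table.index) == ["c", "a", "b", "d"]
        assert list(table["rank"]) == [1, 2, 3, 4]


class TestLinkPartition:
    def test_toy_counts(self):
        groups = {"a": G2, "b": G2, "c": G6, "d": G6}
        net = make_network([("a", "b"), ("c", "d"), ("b", "c")], groups)
        stats = count_links_by_group(net)
        assert stats.within_total == 2
        assert stats.between_total == 1
        assert stats.counts.at["G2", "G6"] == 1
        assert stats.counts.at["G6", "G2"] == 1

    def test_single_group_has_no_between(self):
        net = make_network([("a", "b"), ("b", "c")], {v: G2 for v in "abc"})
        stats = count_links_by_group(net)
        assert stats.between_total == 0
        assert stats.within_total == net.n_edges

    def test_totals_equal_edge_scan(self, rng):
        truth = make_truth({G2: 10, G6: 10})
        edges = generate_network(truth, p_in=0.5, p_out=0.2, p_decoy=0.0, seed=11)
        net = build_network(edges, truth.modules.keys(), truth.groups)
        stats = count_links_by_group(net)
        within = sum(
            1 for a, b in net.graph.edges if net.group_of(a) is net.group_of(b)
        )
        assert stats.within_total == within
        assert stats.within_total + stats.between_total == net.n_edges


class TestWithinFractions:
    def test_all_same_group_neighbors(self):
        net = make_network([("a", "b"), ("a", "c")], {v: G2 for v in "abc"})
        assert (within_fraction_per_gene(net) == 1.0).all()

    def test_expected_two_groups_of_two(self):
        groups = {"a": G2, "b": G2, "c": G6, "d": G6}
        net = make_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")], groups)
        assert np.allclose(expected_within_fraction(net), 1 / 3)

    def test_label_shuffle_consistency(self, rng):
        # mean observed under shuffled labels matches the analytic expectation
        truth = make_truth({G2: 12, G6: 8})
        edges = generate_network(truth, p_in=0.4, p_out=0.4, p_decoy=0.0, seed=2)
        net = build_network(edges, truth.modules.keys(), truth.groups)
        exp_mean = expected_within_fraction(net).mean()
        nodes = net.nodes
        labels = [net.group_of(v) for v in nodes]
        means = []
        for _ in range(200):
            perm = rng.permutation(len(nodes))
            shuffled = dict(zip(nodes, (labels[i] for i in perm)))
            for v in nodes:
                net.graph.nodes[v]["group"] = shuffled[v]
            means.append(within_fraction_per_gene(net).mean())
        assert np.mean(means) == pytest.approx(exp_mean, abs=0.02)


class TestLikelihoodScore:
    def test_complete_graph_scores_one(self):
        nodes = ["a", "b", "c", "d", "e", "f"]
        groups = {v: (G2 if i < 3 else G6) for i, v in enumerate(nodes)}
        pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
        net = make_network(pairs, groups)
        score, p = likelihood_score(net)
        assert score == pytest.approx(1.0)

    def test_rewiring_within_increases_score(self):
        groups = {v: (G2 if v in "ab" else G6) for v in "abcd"}
        mixed = make_network([("a", "c"), ("b", "d"), ("a", "d"), ("b", "c")], groups)
        sorted_net = make_network(
            [("a", "b"), ("c", "d"), ("a", "c"), ("b", "d")], groups
        )
        assert likelihood_score(sorted_net)[0] > likelihood_score(mixed)[0]


class TestPermutationNull:
    def _modular_net(self, seed=3):
        truth = make_truth({G2: 12, G6: 12})
        edges = generate_network(truth, p_in=0.8, p_out=0.02, p_decoy=0.0, seed=seed)
        return build_network(edges, truth.modules.keys(), truth.groups)

    def test_strong_modularity_minimal_p(self):
        net = self._modular_net()
        null = permutation_null(net, n_perm=100, seed=0)
        assert null.p_value == pytest.approx(1 / 101)

    def test_same_seed_identical(self):
        net = self._modular_net()
        a = permutation_null(net, n_perm=100, seed=42)
        b = permutation_null(net, n_perm=100, seed=42)
        assert np.array_equal(a.null_scores, b.null_scores)

    def test_too_few_permutations_rejected(self):
        net = self._modular_net()
        with pytest.raises(ValueError):
            permutation_null(net, n_perm=50, seed=0)
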