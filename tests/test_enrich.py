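"""Curated-set mapping, centrality comparison and top-tier enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import make_network, random_graph_network
from patternet.enrich import (
    compare_centrality,
    enrichment_result,
    fold_enrichment,
    hypergeom_enrichment,
    map_gene_set,
    select_candidates,
    top_fraction,
)
from patternet.io import CuratedGeneSet
from patternet.network import betweenness_centrality
from patternet.patterns import PatternGroup, RatioProfile

G2 = PatternGroup.G2


def bc_table_from_values(values, degrees=None):
    nodes = list(values)
    df = pd.DataFrame(
        {
            "raw_bc": [values[v] for v in nodes],
            "bc": [values[v] for v in nodes],
            "degree": [1 if degrees is None else degrees[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    order = sorted(nodes, key=lambda v: (-df.at[v, "bc"], -df.at[v, "degree"], v))
    df["rank"] = pd.Series({v: i + 1 for i, v in enumerate(order)})
    return df.sort_values("rank")


class TestMapGeneSet:
    def test_disjoint_list_maps_nothing(self):
        net = make_network([("a", "b")], {"a": G2, "b": G2})
        flags, rate = map_gene_set(net, CuratedGeneSet(frozenset({"zzz"})))
        assert not any(flags.values()) and rate == 0.0

    def test_superset_maps_everything(self):
        net = make_network([("a", "b")], {"a": G2, "b": G2})
        flags, rate = map_gene_set(
            net, CuratedGeneSet(frozenset({"a", "b", "c", "d"}))
        )
        assert all(flags.values()) and rate == 0.5

    def test_case_insensitive(self):
        net = make_network([("Akt1", "Src")], {"Akt1": G2, "Src": G2})
        flags, _ = map_gene_set(net, CuratedGeneSet(frozenset({"akt1"})))
        assert flags["Akt1"] and not flags["Src"]


class TestCompareCentrality:
    def test_identical_values_p_one(self):
        table = bc_table_from_values({f"v{i}": 0.5 for i in range(6)})
        flags = {f"v{i}": i < 3 for i in range(6)}
        _, _, p = compare_centrality(table, flags)
        assert p == 1.0

    def test_top_block_against_exact_enumeration(self):
        # curated = top 5 of 20 distinct values; oracle = full enumeration
        values = {f"v{i:02d}": (20 - i) / 20 for i in range(20)}
        table = bc_table_from_values(values)
        flags = {v: values[v] > 15 / 20 for v in values}
        mean_c, mean_o, p = compare_centrality(table, flags)
        assert mean_c > mean_o
        xs = sorted(values.values(), reverse=True)
        n1 = 5

        def u_of(chosen):
            rest = [x for i, x in enumerate(xs) if i not in chosen]
            return sum(1 for i in chosen for b in rest if xs[i] > b)

        mu = n1 * 15 / 2
        u_obs = u_of(tuple(range(5)))
        total = extreme = 0
        for chosen in combinations(range(20), n1):
            total += 1
            if abs(u_of(chosen) - mu) >= abs(u_obs - mu) - 1e-9:
                extreme += 1
        p_exact = extreme / total
        # normal approximation with continuity correction tracks the exact tail
        assert p == pytest.approx(p_exact, abs=0.02)

    def test_empty_class_rejected(self):
        table = bc_table_from_values({"a": 0.1, "b": 0.2})
        with pytest.raises(ValueError):
            compare_centrality(table, {"a": True, "b": True})


class TestTopFraction:
    def test_floor_rule_432_to_43(self):
        values = {f"g{i:03d}": 1.0 - i / 1000 for i in range(432)}
        table = bc_table_from_values(values)
        assert len(top_fraction(table, 0.1)) == 43

    def test_minimum_one_node(self):
        table = bc_table_from_values({f"g{i}": i / 10 for i in range(10)})
        assert len(top_fraction(table, 0.05)) == 1

    def test_equals_sort_and_slice(self, rng):
        values = {f"g{i}": float(v) for i, v in enumerate(rng.random(50))}
        table = bc_table_from_values(values)
        expected = sorted(values, key=values.get, reverse=True)[:5]
        assert top_fraction(table, 0.1) == expected

    def test_all_ties_follow_rank_rule(self):
        values = {v: 0.3 for v in "fbeacd"}
        degrees = {v: 2 for v in "fbeacd"}
        degrees["e"] = 5
        table = bc_table_from_values(values, degrees)
        # ties break by degree then lexicographic id
        assert top_fraction(table, 0.35) == ["e", "a"]

    def test_bad_fraction_rejected(self):
        table = bc_table_from_values({"a": 0.1})
        with pytest.raises(ValueError):
            top_fraction(table, 0.0)


class TestFoldEnrichment:
    def test_reported_counts(self):
        assert fold_enrichment(17, 43, 82, 432) == pytest.approx(2.083, abs=5e-4)

    def test_proportional_tier_is_unity(self):
        assert fold_enrichment(5, 10, 50, 100) == pytest.approx(1.0)
        assert fold_enrichment(10, 10, 100, 100) == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(1, 0, 5, 10)
        with pytest.raises(ValueError):
            fold_enrichment(6, 5, 5, 10)


class TestHypergeomEnrichment:
    def test_small_exact(self):
        assert hypergeom_enrichment(2, 3, 4, 10) == pytest.approx(1 / 3)

    def test_k_zero(self):
        assert hypergeom_enrichment(0, 5, 10, 50) == 1.0

    def test_relabeling_invariance(self):
        net = random_graph_network(8, 0.5, 21)
        table = betweenness_centrality(net)
        curated = CuratedGeneSet(frozenset(list(net.nodes)[:3]))
        r1 = enrichment_result(net, table, curated, 0.3)
        mapping = {v: f"w{i}" for i, v in enumerate(net.nodes)}
        from patternet.io import InteractionEdge
        from patternet.network import build_network

        net2 = build_network(
            [InteractionEdge(mapping[a], mapping[b], 700) for a, b in net.graph.edges],
            mapping.values(),
            {m: G2 for m in mapping.values()},
        )
        table2 = betweenness_centrality(net2)
        curated2 = CuratedGeneSet(frozenset(mapping[v] for v in curated.symbols))
        r2 = enrichment_result(net2, table2, curated2, 0.3)
        assert r1.fold_enrichment == pytest.approx(r2.fold_enrichment)
        assert r1.hypergeom_p == pytest.approx(r2.hypergeom_p)


class TestSelectCandidates:
    def _setup(self):
        pairs = [("hub", l) for l in ("a", "b", "c", "d")] + [("a", "b")]
        groups = {v: G2 for v in ("hub", "a", "b", "c", "d")}
        net = make_network(pairs, groups)
        table = betweenness_centrality(net)
        profiles = [
            RatioProfile(v, (1,), (1.5,), (0.5,), 1.5, 0.75)
            for v in ("hub", "a", "b", "c", "d")
        ]
        flags = {v: v == "hub" for v in ("hub", "a", "b", "c", "d")}
        return net, table, profiles, flags

    def test_record_count_and_rank(self):
        net, table, profiles, flags = self._setup()
        records = select_candidates(net, table, profiles, flags, 0.4)
        assert len(records) == 2
        assert records[0].gene == "hub" and records[0].rank == 1
        assert records[0].curated and records[0].group is G2

    def test_missing_profile_names_node(self):
        net, table, profiles, flags = self._setup()
        with pytest.raises(ValueError, match="hub"):
            select_candidates(net, table, profiles[1:], flags, 0.4)

    def test_stable_output_bytes(self, tmp_path):
        from patternet.io import write_candidate_table

        net, table, profiles, flags = self._setup()
        records = select_candidates(net, table, profiles, flags, 0.4)
        p1, p2 = tmp_path / "c1.tsv", tmp_path / "c2.tsv"
        write_candidate_table(records, p1)
        write_candidate_table(
            select_candidates(net, table, profiles, flags, 0.4), p2
        )
        assert p1.read_bytes() == p2.read_bytes()
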