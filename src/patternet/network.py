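"""Seed-gene network construction and topology statistics.

The patterned genes act as seeds; the score-filtered interaction edges are
restricted to the seed set, isolated seeds are dropped, and the resulting
undirected simple graph carries a pattern-group label (and optionally a
curated flag) per node. On that graph we compute:

* betweenness centrality (Brandes accumulation over unweighted shortest
  paths, normalised by (n-1)(n-2)/2 pairs), plus an exhaustive
  path-enumeration oracle for small graphs;
* within/between group link counts and the per-gene fraction of same-group
  neighbours against its random-neighbour expectation;
* a likelihood score (mean observed within-fraction over mean expected) with
  a Mann-Whitney U p-value and a label-permutation null.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import InteractionEdge, normalize_symbol
from .patterns import PatternGroup
from .stats import mann_whitney_u

__all__ = [
    "GeneNetwork",
    "LinkPartitionStats",
    "PermutationNull",
    "build_network",
    "betweenness_centrality",
    "brute_force_betweenness",
    "count_links_by_group",
    "within_fraction_per_gene",
    "expected_within_fraction",
    "likelihood_score",
    "permutation_null",
]

_GROUP_ORDER = [g for g in PatternGroup if g is not PatternGroup.NONE]


@dataclass
class GeneNetwork:
    """Undirected simple graph over seed genes with node annotations.

    Node attributes: ``group`` (PatternGroup) and ``curated`` (bool). Every
    node has degree >= 1 — isolated seeds are excluded at construction.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def group_of(self, node: str) -> PatternGroup:
        return self.graph.nodes[node]["group"]

    def groups(self) -> dict[str, PatternGroup]:
        return {v: d["group"] for v, d in self.graph.nodes(data=True)}

    def curated_flags(self) -> dict[str, bool]:
        return {v: bool(d.get("curated", False)) for v, d in self.graph.nodes(data=True)}


def build_network(
    edges: Iterable[InteractionEdge],
    seed_genes: Iterable[str],
    groups: Mapping[str, PatternGroup] | None = None,
    curated: Iterable[str] | None = None,
) -> GeneNetwork:
    """Induce the interaction graph on the seed genes.

    Edges whose two endpoints both match seed genes (case-insensitively) are
    kept; seeds with no qualifying edge never enter the graph. ``groups``
    labels nodes with their pattern group, ``curated`` flags curated nodes.
    """
    seed_by_norm = {normalize_symbol(g): g for g in seed_genes}
    group_by_norm = (
        {normalize_symbol(g): grp for g, grp in groups.items()} if groups else {}
    )
    curated_norm = {normalize_symbol(c) for c in curated} if curated else set()
    G = nx.Graph()
    for e in edges:
        na, nb = normalize_symbol(e.node_a), normalize_symbol(e.node_b)
        if na in seed_by_norm and nb in seed_by_norm and na != nb:
            G.add_edge(seed_by_norm[na], seed_by_norm[nb], score=e.combined_score)
    if G.number_of_nodes() == 0:
        raise ValueError("no interaction edges connect the seed genes")
    for v in G.nodes:
        nv = normalize_symbol(v)
        G.nodes[v]["group"] = group_by_norm.get(nv, PatternGroup.NONE)
        G.nodes[v]["curated"] = nv in curated_norm
    return GeneNetwork(G)


# ---------------------------------------------------------------------------
# Betweenness centrality
# ---------------------------------------------------------------------------


def _brandes_raw(G: nx.Graph) -> dict[str, float]:
    """Raw betweenness over unordered pairs via Brandes' accumulation."""
    bc = dict.fromkeys(G, 0.0)
    for s in G:
        stack: list = []
        preds: dict = {v: [] for v in G}
        sigma = dict.fromkeys(G, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in G[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(G, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was visited from both endpoints
    return {v: b / 2.0 for v, b in bc.items()}


def _centrality_table(raw: dict[str, float], G: nx.Graph) -> pd.DataFrame:
    n = G.number_of_nodes()
    norm = (n - 1) * (n - 2) / 2.0
    rows = []
    for v in G.nodes:
        value = raw[v] / norm if n >= 3 else 0.0
        rows.append((v, raw[v], value, G.degree[v]))
    table = pd.DataFrame(rows, columns=["node", "raw_bc", "bc", "degree"]).set_index(
        "node"
    )
    order = sorted(
        table.index, key=lambda v: (-table.at[v, "bc"], -table.at[v, "degree"], v)
    )
    table["rank"] = pd.Series(
        {v: i + 1 for i, v in enumerate(order)}, name="rank"
    ).astype(int)
    return table.sort_values("rank")


def betweenness_centrality(net: GeneNetwork) -> pd.DataFrame:
    """Centrality table: raw and normalised BC, degree, rank per node.

    Normalised BC divides by (n-1)(n-2)/2 with n the global node count, also
    for disconnected graphs. Rank 1 is the largest normalised BC; ties break
    by higher degree, then lexicographic node ID.
    """
    return _centrality_table(_brandes_raw(net.graph), net.graph)


_BRUTE_FORCE_CAP = 12


def brute_force_betweenness(net: GeneNetwork) -> pd.DataFrame:
    """Oracle BC by explicit enumeration of every shortest path (<= 12 nodes)."""
    G = net.graph
    if G.number_of_nodes() > _BRUTE_FORCE_CAP:
        raise ValueError(
            f"brute-force oracle capped at {_BRUTE_FORCE_CAP} nodes, "
            f"got {G.number_of_nodes()}"
        )
    raw = dict.fromkeys(G, 0.0)
    nodes = list(G.nodes)
    for i, s in enumerate(nodes):
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in G[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        for t in nodes[i + 1 :]:
            if t not in dist:
                continue
            paths: list[list[str]] = []

            def walk(v: str, acc: list[str]) -> None:
                if v == s:
                    paths.append(acc)
                    return
                for u in G[v]:
                    if u in dist and dist[u] == dist[v] - 1:
                        walk(u, acc + [u])

            walk(t, [t])
            for p in paths:
                for v in p[1:-1]:
                    raw[v] += 1.0 / len(paths)
    return _centrality_table(raw, G)


# ---------------------------------------------------------------------------
# Link partition statistics
# ---------------------------------------------------------------------------


@dataclass
class LinkPartitionStats:
    """Within/between-group link counts for a fully labelled network."""

    counts: pd.DataFrame  # symmetric 6x6 group-pair matrix
    within_total: int
    between_total: int


def count_links_by_group(net: GeneNetwork) -> LinkPartitionStats:
    """Tally edges by the (group, group) pair of their endpoints."""
    names = [g.value for g in _GROUP_ORDER]
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    within = between = 0
    for a, b in net.graph.edges:
        ga, gb = net.group_of(a), net.group_of(b)
        if ga is PatternGroup.NONE or gb is PatternGroup.NONE:
            raise ValueError(f"edge {a}-{b} touches an unlabelled node")
        counts.at[ga.value, gb.value] += 1
        if ga is not gb:
            counts.at[gb.value, ga.value] += 1
            between += 1
        else:
            within += 1
    return LinkPartitionStats(counts, within, between)


def within_fraction_per_gene(net: GeneNetwork) -> pd.Series:
    """Observed fraction of each node's neighbours sharing its group."""
    out = {}
    for v in net.graph.nodes:
        gv = net.group_of(v)
        if gv is PatternGroup.NONE:
            raise ValueError(f"node {v} has no group label")
        nbrs = list(net.graph[v])
        same = sum(1 for w in nbrs if net.group_of(w) is gv)
        out[v] = same / len(nbrs)
    return pd.Series(out, name="observed_within").sort_index()


def expected_within_fraction(net: GeneNetwork) -> pd.Series:
    """Random-neighbour expectation (n_g - 1)/(N - 1) per node."""
    groups = net.groups()
    sizes: dict[PatternGroup, int] = {}
    for g in groups.values():
        sizes[g] = sizes.get(g, 0) + 1
    N = net.n_nodes
    if N < 2:
        raise ValueError("expected within-fraction undefined for N < 2")
    out = {v: (sizes[g] - 1) / (N - 1) for v, g in groups.items()}
    return pd.Series(out, name="expected_within").sort_index()


def likelihood_score(net: GeneNetwork) -> tuple[float, float]:
    """Within-group clustering strength and its Mann-Whitney U p-value.

    Score = mean(observed within-fraction) / mean(expected within-fraction);
    the p-value compares the two per-gene vectors (unpaired, two-sided).
    """
    obs = within_fraction_per_gene(net)
    exp = expected_within_fraction(net)
    mean_exp = float(exp.mean())
    if mean_exp == 0:
        raise ValueError("expected within-fraction is zero; score undefined")
    score = float(obs.mean()) / mean_exp
    p = mann_whitney_u(obs.to_numpy(), exp.to_numpy()).p_value
    return score, p


@dataclass
class PermutationNull:
    """Label-permutation null distribution of the likelihood score."""

    observed: float
    null_scores: np.ndarray
    p_value: float  # (1 + #{null >= observed}) / (n_perm + 1)


def permutation_null(
    net: GeneNetwork, n_perm: int = 1000, seed: int | None = None
) -> PermutationNull:
    """Recompute the likelihood score under group-size-preserving label shuffles."""
    if n_perm < 100:
        raise ValueError(f"n_perm must be at least 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    nodes = net.nodes
    index = {v: i for i, v in enumerate(nodes)}
    labels = np.array([_GROUP_ORDER.index(net.group_of(v)) for v in nodes])
    deg = np.array([net.graph.degree[v] for v in nodes], dtype=float)
    nbr_flat = np.concatenate(
        [np.fromiter((index[w] for w in net.graph[v]), dtype=int) for v in nodes]
    )
    offsets = np.concatenate([[0], np.cumsum(deg.astype(int))[:-1]])
    owner = np.repeat(np.arange(len(nodes)), deg.astype(int))

    # mean expected within-fraction depends only on group sizes: constant
    exp_mean = float(expected_within_fraction(net).mean())

    def score_for(lab: np.ndarray) -> float:
        same = lab[nbr_flat] == lab[owner]
        obs = np.add.reduceat(same, offsets) / deg
        return float(obs.mean()) / exp_mean

    observed = score_for(labels)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = score_for(rng.permutation(labels))
    p = (1.0 + float((null >= observed - 1e-12).sum())) / (n_perm + 1.0)
    return PermutationNull(observed, null, p)
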