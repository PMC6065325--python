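"""Curated-gene-set mapping and top-centrality-tier enrichment.

Given the seed-gene network and its centrality table, map a curated gene
list onto the nodes, compare centrality between curated and other genes,
take the top fraction of nodes by betweenness (m = floor(frac * N), at least
one node), and test whether curated genes are over-represented in that tier
with a one-sided hypergeometric test. The ranked tier joined with pattern
groups and normalised fold-changes is the pipeline's candidate report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import CandidateRecord, CuratedGeneSet, normalize_symbol
from .network import GeneNetwork
from .patterns import RatioProfile
from .stats import hypergeom_sf, mann_whitney_u

__all__ = [
    "EnrichmentResult",
    "map_gene_set",
    "compare_centrality",
    "top_fraction",
    "fold_enrichment",
    "hypergeom_enrichment",
    "enrichment_result",
    "select_candidates",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts and statistics of curated-gene enrichment in the top BC tier."""

    N: int  # network nodes
    K: int  # curated nodes in the network
    m: int  # top-tier size
    k: int  # curated nodes in the top tier
    mapping_rate: float  # K / size of the curated list
    fold_enrichment: float  # (k/m) / (K/N)
    hypergeom_p: float
    bc_mwu_p: float
    mean_bc_curated: float
    mean_bc_other: float


def map_gene_set(
    net: GeneNetwork, curated: CuratedGeneSet
) -> tuple[dict[str, bool], float]:
    """Flag network nodes present in the curated list; rate = mapped / list size."""
    flags = {v: normalize_symbol(v) in curated.symbols for v in net.nodes}
    mapped = sum(flags.values())
    return flags, mapped / len(curated)


def compare_centrality(
    bc_table: pd.DataFrame, flags: Mapping[str, bool]
) -> tuple[float, float, float]:
    """Mean normalised BC of curated vs other nodes with a two-sided MWU p."""
    curated = [v for v in bc_table.index if flags.get(v, False)]
    other = [v for v in bc_table.index if not flags.get(v, False)]
    if not curated or not other:
        raise ValueError("both curated and non-curated classes must be non-empty")
    x = bc_table.loc[curated, "bc"].to_numpy()
    y = bc_table.loc[other, "bc"].to_numpy()
    res = mann_whitney_u(x, y)
    return float(x.mean()), float(y.mean()), res.p_value


def top_fraction(bc_table: pd.DataFrame, frac: float = 0.1) -> list[str]:
    """Top floor(frac * N) nodes by rank (minimum one node)."""
    if not 0 < frac < 1:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    n = len(bc_table)
    if n == 0:
        raise ValueError("empty centrality table")
    m = max(1, math.floor(frac * n))
    return list(bc_table.sort_values("rank").index[:m])


def fold_enrichment(k: int, m: int, K: int, N: int) -> float:
    """Tier curated proportion over network curated proportion: (k/m)/(K/N)."""
    if m <= 0 or K <= 0:
        raise ValueError(f"fold enrichment undefined for m={m}, K={K}")
    if not (0 <= k <= min(m, K) and m <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, m={m}, K={K}, N={N}")
    return (k / m) / (K / N)


def hypergeom_enrichment(k: int, m: int, K: int, N: int) -> float:
    """One-sided over-representation p-value P(X >= k), X ~ HG(N, K, m)."""
    return hypergeom_sf(k, N, K, m)


def enrichment_result(
    net: GeneNetwork,
    bc_table: pd.DataFrame,
    curated: CuratedGeneSet,
    frac: float = 0.1,
) -> EnrichmentResult:
    """Full enrichment summary for a curated list on a scored network."""
    flags, mapping_rate = map_gene_set(net, curated)
    N = net.n_nodes
    K = sum(flags.values())
    tier = top_fraction(bc_table, frac)
    m = len(tier)
    k = sum(1 for v in tier if flags[v])
    mean_c, mean_o, mwu_p = compare_centrality(bc_table, flags)
    return EnrichmentResult(
        N=N,
        K=K,
        m=m,
        k=k,
        mapping_rate=mapping_rate,
        fold_enrichment=fold_enrichment(k, m, K, N),
        hypergeom_p=hypergeom_enrichment(k, m, K, N),
        bc_mwu_p=mwu_p,
        mean_bc_curated=mean_c,
        mean_bc_other=mean_o,
    )


def select_candidates(
    net: GeneNetwork,
    bc_table: pd.DataFrame,
    profiles: Iterable[RatioProfile] | Mapping[str, RatioProfile],
    flags: Mapping[str, bool],
    frac: float = 0.1,
) -> list[CandidateRecord]:
    """Rank the top BC tier and join group labels, curated flags and ratios."""
    if isinstance(profiles, Mapping):
        by_gene = {normalize_symbol(g): p for g, p in profiles.items()}
    else:
        by_gene = {normalize_symbol(p.gene): p for p in profiles}
    tier = top_fraction(bc_table, frac)
    records = []
    for rank, node in enumerate(tier, start=1):
        prof = by_gene.get(normalize_symbol(node))
        if prof is None:
            raise ValueError(f"no ratio profile for network node {node}")
        records.append(
            CandidateRecord(
                rank=rank,
                gene=node,
                bc=float(bc_table.at[node, "bc"]),
                curated=bool(flags.get(node, False)),
                group=net.group_of(node),
                norm_masa=prof.norm_masa,
                norm_wd=prof.norm_wd,
            )
        )
    return records
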