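"""Synthetic study bundles with known ground truth.

Emulates the three inputs of the prioritization pipeline so every stage is
testable without external data:

* a paired FPKM-like expression matrix (3 rats by default) with six planted
  ratio-pattern groups in the published proportions (3:422:2:51:25:163 among
  patterned genes) and multiplicative log-normal noise;
* a stochastic-block-model interaction network whose modules coincide with
  the planted pattern groups (unpatterned genes form a background block that
  only receives between-module edges), with confidence scores in [400, 999]
  plus sub-threshold decoy edges in [100, 399];
* a curated gene list planted uniformly or degree-biased (weight ∝ degree^β)
  on the network nodes, optionally padded with off-network symbols to emulate
  a large knowledgebase of which only a few percent map onto the network.

Everything is deterministic given a master seed; the three components consume
independent substreams so stages can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CuratedGeneSet,
    ExpressionMatrix,
    InteractionEdge,
    write_expression_table,
    write_gene_set,
    write_string_links,
)
from .patterns import PatternGroup

__all__ = [
    "ExpressionParams",
    "NetworkParams",
    "CuratedParams",
    "StudyConfig",
    "StudyBundle",
    "SyntheticTruth",
    "generate_expression",
    "generate_network",
    "plant_curated_set",
    "generate_study",
]

_PATTERN_DIRECTIONS: dict[PatternGroup, tuple[int, int]] = {
    PatternGroup.G1: (1, 1),
    PatternGroup.G2: (1, -1),
    PatternGroup.G3: (0, 1),
    PatternGroup.G4: (0, -1),
    PatternGroup.G5: (-1, 1),
    PatternGroup.G6: (-1, -1),
}
_GROUPS = tuple(_PATTERN_DIRECTIONS)

BACKGROUND_MODULE = "BG"


@dataclass(frozen=True)
class ExpressionParams:
    """Knobs of the expression generator.

    ``group_weights`` are the relative sizes of G1..G6 among patterned genes;
    ``patterned_fraction`` of all genes carry a pattern (the rest are flat).
    Up/down effects are multiplicative fold-changes per step, drawn uniformly
    from the given ranges; ``sigma`` is the log-scale noise s.d. per value.
    """

    n_genes: int = 2000
    n_rats: int = 3
    patterned_fraction: float = 0.333
    group_weights: tuple[float, ...] = (3, 422, 2, 51, 25, 163)
    up_range: tuple[float, float] = (1.2, 4.0)
    down_range: tuple[float, float] = (0.25, 0.83)
    sigma: float = 0.1
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.2


@dataclass(frozen=True)
class NetworkParams:
    """Stochastic-block-model parameters for the interaction network."""

    p_in: float = 0.008
    p_out: float = 0.0055
    p_decoy: float = 0.05
    score_range: tuple[int, int] = (400, 999)
    decoy_range: tuple[int, int] = (100, 399)


@dataclass(frozen=True)
class CuratedParams:
    """Curated-list planting rule.

    ``size`` is the number of on-network genes (default ~19% of network
    nodes); off-network symbols pad the list so that the on-network mapping
    rate is about ``mapping_rate`` unless ``n_off_network`` is given.
    """

    rule: str = "degree_biased"
    beta: float = 2.0
    size: int | None = None
    n_off_network: int | None = None
    mapping_rate: float = 0.065
    on_network_fraction: float = 0.19


@dataclass(frozen=True)
class StudyConfig:
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    curated: CuratedParams = field(default_factory=CuratedParams)
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic bundle."""

    groups: dict[str, PatternGroup]  # every gene; NONE for flat genes
    effects: dict[str, tuple[float, float]]  # per-step fold-changes (e1, e2)
    modules: dict[str, str]  # pattern-group value or BACKGROUND_MODULE
    params: dict
    seed: int | None
    curated_on_network: list[str] = field(default_factory=list)

    def patterned_genes(self) -> list[str]:
        return [g for g, grp in self.groups.items() if grp is not PatternGroup.NONE]


def _apportion(weights: Sequence[float], total: int) -> list[int]:
    """Largest-remainder apportionment of `total` among `weights`."""
    weights = np.asarray(weights, dtype=float)
    quotas = weights / weights.sum() * total
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def generate_expression(
    params: ExpressionParams, seed=None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a paired three-timepoint matrix with planted pattern groups.

    CON means are log-normal baselines; MASA means multiply the baseline by
    the step-1 effect and WD means by both effects. Each observed value is
    its mean times exp(N(0, sigma^2)).
    """
    if params.n_genes < 10:
        raise ValueError("n_genes must be at least 10")
    if params.n_rats < 2:
        raise ValueError("n_rats must be at least 2")
    if params.sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if not 0 <= params.patterned_fraction <= 1:
        raise ValueError("patterned_fraction (sum of group proportions) must be <= 1")
    rng = np.random.default_rng(seed)
    n = params.n_genes
    genes = [f"gene{i:05d}" for i in range(n)]
    n_patterned = int(round(params.patterned_fraction * n))
    counts = _apportion(params.group_weights, n_patterned)
    labels = np.concatenate(
        [np.full(c, gi, dtype=int) for gi, c in enumerate(counts)]
        + [np.full(n - n_patterned, -1, dtype=int)]
    )
    rng.shuffle(labels)

    def draw_effect(direction: int) -> float:
        if direction == 1:
            return float(rng.uniform(*params.up_range))
        if direction == -1:
            return float(rng.uniform(*params.down_range))
        return 1.0

    groups: dict[str, PatternGroup] = {}
    effects: dict[str, tuple[float, float]] = {}
    modules: dict[str, str] = {}
    e1 = np.ones(n)
    e2 = np.ones(n)
    for i, gene in enumerate(genes):
        if labels[i] >= 0:
            grp = _GROUPS[labels[i]]
            d1, d2 = _PATTERN_DIRECTIONS[grp]
            e1[i], e2[i] = draw_effect(d1), draw_effect(d2)
            groups[gene] = grp
            modules[gene] = grp.value
        else:
            groups[gene] = PatternGroup.NONE
            modules[gene] = BACKGROUND_MODULE
        effects[gene] = (float(e1[i]), float(e2[i]))

    base = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd, n))
    means = {
        "CON": base,
        "MASA": base * e1,
        "WD": base * e1 * e2,
    }
    rats = list(range(1, params.n_rats + 1))
    blocks = {}
    for tp in ("CON", "MASA", "WD"):
        noise = rng.normal(0.0, params.sigma, (n, params.n_rats))
        blocks[tp] = means[tp][:, None] * np.exp(noise)
    data = pd.DataFrame(
        np.hstack([blocks[tp] for tp in ("CON", "MASA", "WD")]),
        index=pd.Index(genes, name="gene_id"),
        columns=pd.MultiIndex.from_tuples(
            [(tp, r) for tp in ("CON", "MASA", "WD") for r in rats],
            names=["timepoint", "rat"],
        ),
    )
    truth = SyntheticTruth(
        groups=groups,
        effects=effects,
        modules=modules,
        params={"expression": dataclasses.asdict(params)},
        seed=seed if isinstance(seed, int) else None,
    )
    return ExpressionMatrix(data), truth


def generate_network(
    truth: SyntheticTruth,
    p_in: float = NetworkParams.p_in,
    p_out: float = NetworkParams.p_out,
    p_decoy: float = NetworkParams.p_decoy,
    seed=None,
    score_range: tuple[int, int] = NetworkParams.score_range,
    decoy_range: tuple[int, int] = NetworkParams.decoy_range,
) -> list[InteractionEdge]:
    """Sample interaction edges from a stochastic block model on the genes.

    Within-module pairs (module = planted pattern group) are edges with
    probability p_in, all other pairs — including every pair touching the
    background block — with p_out. Qualifying edges get scores uniform in
    ``score_range``; non-edges become sub-threshold decoys at rate p_decoy.
    """
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError(f"need 0 <= p_out <= p_in <= 1, got p_in={p_in}, p_out={p_out}")
    if not 0 <= p_decoy <= 1:
        raise ValueError(f"p_decoy must be in [0, 1], got {p_decoy}")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.modules)
    mods = np.array([truth.modules[g] for g in genes])
    mod_ids = np.searchsorted(np.unique(mods), mods)
    background = mods == BACKGROUND_MODULE
    ii, jj = np.triu_indices(len(genes), k=1)
    same = (mod_ids[ii] == mod_ids[jj]) & ~background[ii] & ~background[jj]
    prob = np.where(same, p_in, p_out)
    is_edge = rng.random(ii.size) < prob
    is_decoy = ~is_edge & (rng.random(ii.size) < p_decoy)
    edges: list[InteractionEdge] = []
    scores = rng.integers(score_range[0], score_range[1] + 1, int(is_edge.sum()))
    for (i, j), s in zip(zip(ii[is_edge], jj[is_edge]), scores):
        edges.append(InteractionEdge(genes[i], genes[j], int(s)))
    decoy_scores = rng.integers(decoy_range[0], decoy_range[1] + 1, int(is_decoy.sum()))
    for (i, j), s in zip(zip(ii[is_decoy], jj[is_decoy]), decoy_scores):
        edges.append(InteractionEdge(genes[i], genes[j], int(s)))
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    return edges


def _network_degrees(
    edges: Sequence[InteractionEdge], score_min: int = 400
) -> dict[str, int]:
    deg: dict[str, int] = {}
    for e in edges:
        if e.combined_score >= score_min:
            deg[e.node_a] = deg.get(e.node_a, 0) + 1
            deg[e.node_b] = deg.get(e.node_b, 0) + 1
    return deg


def plant_curated_set(
    edges: Sequence[InteractionEdge],
    size: int,
    rule: str = "uniform",
    beta: float = 1.0,
    n_off_network: int = 0,
    seed=None,
    score_min: int = 400,
) -> tuple[CuratedGeneSet, list[str]]:
    """Sample a curated list over the network's nodes.

    ``uniform`` draws nodes uniformly without replacement; ``degree_biased``
    draws with probability proportional to degree^beta (beta > 0 concentrates
    the list on hubs). ``n_off_network`` extra symbols never occurring in the
    network are appended. Returns the gene set and the on-network members.
    """
    if rule not in ("uniform", "degree_biased"):
        raise ValueError(f"unknown planting rule {rule!r}")
    if beta < 0:
        raise ValueError(f"beta must be nonnegative, got {beta}")
    if n_off_network < 0:
        raise ValueError("n_off_network must be nonnegative")
    rng = np.random.default_rng(seed)
    degrees = _network_degrees(edges, score_min)
    nodes = sorted(degrees)
    if size > len(nodes):
        raise ValueError(f"size {size} exceeds {len(nodes)} network nodes")
    if size < 0:
        raise ValueError("size must be nonnegative")
    if rule == "uniform":
        chosen = list(rng.choice(nodes, size=size, replace=False)) if size else []
    else:
        weights = np.array([degrees[v] for v in nodes], dtype=float) ** beta
        probs = weights / weights.sum()
        chosen = (
            list(rng.choice(nodes, size=size, replace=False, p=probs)) if size else []
        )
    off = [f"offnet{i:05d}" for i in range(n_off_network)]
    symbols = [str(c) for c in chosen] + off
    if not symbols:
        raise ValueError("curated set would be empty")
    gene_set = CuratedGeneSet(
        frozenset(s.casefold() for s in symbols), {"synthetic": len(symbols)}
    )
    return gene_set, [str(c) for c in chosen]


@dataclass
class StudyBundle:
    """File paths and ground truth of one generated study."""

    expression_path: Path
    links_path: Path
    gene_set_path: Path
    truth_path: Path
    truth: SyntheticTruth
    matrix: ExpressionMatrix
    edges: list[InteractionEdge]
    curated: CuratedGeneSet


def generate_study(config: StudyConfig, out_dir: str | Path) -> StudyBundle:
    """Generate and write a full bundle: expression, links, curated list, truth.

    The master seed feeds three fixed-order substreams (expression, network,
    curated) so identical configs give byte-identical bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed).spawn(3)
    matrix, truth = generate_expression(config.expression, ss[0])
    truth.seed = config.seed
    edges = generate_network(
        truth,
        p_in=config.network.p_in,
        p_out=config.network.p_out,
        p_decoy=config.network.p_decoy,
        seed=ss[1],
        score_range=config.network.score_range,
        decoy_range=config.network.decoy_range,
    )
    degrees = _network_degrees(edges)
    n_nodes = len(degrees)
    if n_nodes == 0:
        raise ValueError("generated network has no qualifying edges")
    cp = config.curated
    size = cp.size if cp.size is not None else max(1, round(cp.on_network_fraction * n_nodes))
    n_off = (
        cp.n_off_network
        if cp.n_off_network is not None
        else max(0, round(size / cp.mapping_rate) - size)
    )
    curated, on_network = plant_curated_set(
        edges, size=size, rule=cp.rule, beta=cp.beta, n_off_network=n_off, seed=ss[2]
    )
    truth.curated_on_network = sorted(on_network)
    truth.params.update(
        {
            "network": dataclasses.asdict(config.network),
            "curated": dataclasses.asdict(cp),
            "seed": config.seed,
        }
    )

    expression_path = out / "expression.tsv"
    links_path = out / "links.tsv"
    gene_set_path = out / "curated_genes.tsv"
    truth_path = out / "truth.json"
    write_expression_table(matrix, expression_path)
    write_string_links(edges, links_path)
    write_gene_set(sorted(curated.symbols), gene_set_path)
    payload = {
        "seed": config.seed,
        "params": truth.params,
        "groups": {g: grp.value for g, grp in sorted(truth.groups.items())},
        "effects": {g: list(e) for g, e in sorted(truth.effects.items())},
        "modules": dict(sorted(truth.modules.items())),
        "curated_on_network": truth.curated_on_network,
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return StudyBundle(
        expression_path,
        links_path,
        gene_set_path,
        truth_path,
        truth,
        matrix,
        edges,
        curated,
    )
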