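"""End-to-end orchestration: files in, report files out.

``run_all`` chains the stages — pattern classification, network construction
and topology, curated-set enrichment, candidate report — reading either a
real input bundle (expression TSV, links file, curated list) or a synthetic
bundle generated on the fly from a config block. Each stage writes plain TSV
or JSON artifacts that are valid inputs to the next stage, and a single
master seed drives every stochastic component through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import enrich as enrich_mod
from . import io as io_mod
from . import network as net_mod
from . import patterns as pat_mod
from . import synth as synth_mod
from .patterns import PatternGroup

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_all", "report_candidates"]

ARTIFACTS = (
    "patterned_genes.tsv",
    "network_edges.tsv",
    "centrality.tsv",
    "link_stats.json",
    "enrichment.json",
    "candidates.tsv",
    "summary.json",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs: inputs (or a synthesis block) and thresholds."""

    expression: str | None = None
    links: str | None = None
    gene_set: str | None = None
    id_map: str | None = None
    synthesis: synth_mod.StudyConfig | None = None
    alpha: float = 0.05
    up_thr: float = 1.1
    down_thr: float = 0.9
    score_min: int = 400
    top_frac: float = 0.1
    pseudocount: float = 0.0
    classify_method: str = "consensus"
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        has_inputs = all(p is not None for p in (self.expression, self.links, self.gene_set))
        some_inputs = any(p is not None for p in (self.expression, self.links, self.gene_set))
        if self.synthesis is not None and some_inputs:
            raise ValueError("config must give input paths or a synthesis block, not both")
        if self.synthesis is None and not has_inputs:
            raise ValueError(
                "config needs either a synthesis block or all of expression/links/gene_set"
            )
        if not self.up_thr > self.down_thr > 0:
            raise ValueError("need up_thr > down_thr > 0")
        for name in ("alpha", "top_frac"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        synth_block = d.pop("synthesis", None)
        if synth_block is not None:
            synth_block = synth_mod.StudyConfig(
                expression=synth_mod.ExpressionParams(
                    **synth_block.get("expression", {})
                ),
                network=synth_mod.NetworkParams(**synth_block.get("network", {})),
                curated=synth_mod.CuratedParams(**synth_block.get("curated", {})),
                seed=synth_block.get("seed", d.get("seed", 0)),
            )
        return cls(synthesis=synth_block, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthesis is not None:
            d["synthesis"] = dataclasses.asdict(self.synthesis)
        return d


@dataclass
class RunReport:
    """Artifact paths plus the machine-readable summary of one run."""

    out_dir: Path
    summary: dict
    candidates: list = field(default_factory=list)


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_all(config: RunConfig, out_dir: str | Path, seed: int | None = None) -> RunReport:
    """Run every stage and write the seven artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_seed = config.seed if seed is None else seed
    perm_seed = np.random.SeedSequence([run_seed, 1]).generate_state(1)[0]

    # stage: inputs -------------------------------------------------------
    try:
        if config.synthesis is not None:
            bundle = synth_mod.generate_study(config.synthesis, out / "bundle")
            expression_path = bundle.expression_path
            links_path = bundle.links_path
            gene_set_path = bundle.gene_set_path
        else:
            expression_path = Path(config.expression)
            links_path = Path(config.links)
            gene_set_path = Path(config.gene_set)
        matrix = io_mod.read_expression_table(expression_path)
        id_map = io_mod.read_id_map(config.id_map) if config.id_map else None
        edges = io_mod.read_string_links(links_path, config.score_min, id_map)
        curated = io_mod.read_gene_set(gene_set_path)
    except (OSError, ValueError) as exc:
        raise PipelineError("inputs", str(exc)) from exc

    # stage: pattern classification --------------------------------------
    try:
        kept, anova_p = pat_mod.anova_filter(matrix, config.alpha)
        profiles = pat_mod.compute_ratio_profiles(matrix, kept, config.pseudocount)
        assignments = pat_mod.classify_profiles(
            profiles, config.up_thr, config.down_thr, config.classify_method
        )
        census = pat_mod.group_census(assignments)
        prof_by_gene = {p.gene: p for p in profiles}
        rows = [
            {
                "gene": g,
                "group": assignments[g].value,
                "norm_masa": prof_by_gene[g].norm_masa,
                "norm_wd": prof_by_gene[g].norm_wd,
                "anova_p": float(anova_p[g]),
            }
            for g in sorted(assignments)
            if assignments[g] is not PatternGroup.NONE
        ]
        patterned = pd.DataFrame(
            rows, columns=["gene", "group", "norm_masa", "norm_wd", "anova_p"]
        )
        patterned.to_csv(out / "patterned_genes.tsv", sep="\t", index=False)
    except ValueError as exc:
        raise PipelineError("classify", str(exc)) from exc

    # stage: network topology --------------------------------------------
    try:
        seed_groups = {
            g: grp for g, grp in assignments.items() if grp is not PatternGroup.NONE
        }
        net = net_mod.build_network(
            edges, seed_groups.keys(), seed_groups, curated=curated.symbols
        )
        edge_rows = [
            {"protein1": a, "protein2": b, "combined_score": d["score"]}
            for a, b, d in sorted(net.graph.edges(data=True))
        ]
        pd.DataFrame(
            edge_rows, columns=["protein1", "protein2", "combined_score"]
        ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        bc_table = net_mod.betweenness_centrality(net)
        bc_table.to_csv(out / "centrality.tsv", sep="\t")
        partition = net_mod.count_links_by_group(net)
        score, mwu_p = net_mod.likelihood_score(net)
        null = net_mod.permutation_null(net, config.n_perm, int(perm_seed))
        link_stats = {
            "within_total": partition.within_total,
            "between_total": partition.between_total,
            "within_fraction_of_links": partition.within_total / max(net.n_edges, 1),
            "group_pair_counts": {
                g: {h: int(partition.counts.at[g, h]) for h in partition.counts.columns}
                for g in partition.counts.index
            },
            "likelihood_score": score,
            "mwu_p": mwu_p,
            "permutation_p": null.p_value,
            "n_perm": config.n_perm,
        }
        _write_json(link_stats, out / "link_stats.json")
    except ValueError as exc:
        raise PipelineError("network", str(exc)) from exc

    # stage: enrichment and candidates -----------------------------------
    try:
        result = enrich_mod.enrichment_result(net, bc_table, curated, config.top_frac)
        _write_json(dataclasses.asdict(result), out / "enrichment.json")
        flags, _ = enrich_mod.map_gene_set(net, curated)
        candidates = enrich_mod.select_candidates(
            net, bc_table, profiles, flags, config.top_frac
        )
        io_mod.write_candidate_table(candidates, out / "candidates.tsv")
    except ValueError as exc:
        raise PipelineError("enrich", str(exc)) from exc

    summary = {
        "config": config.to_dict(),
        "run_seed": run_seed,
        "n_genes": matrix.shape[0],
        "n_anova_kept": len(kept),
        "n_patterned": len(patterned),
        "group_census": {g.value: c for g, c in census.items()},
        "n_network_nodes": net.n_nodes,
        "n_network_edges": net.n_edges,
        "link_stats": link_stats,
        "enrichment": dataclasses.asdict(result),
        "artifacts": list(ARTIFACTS),
    }
    _write_json(summary, out / "summary.json")
    return RunReport(out, summary, candidates)


def report_candidates(
    candidates_path: str | Path,
    out_path: str | Path | None = None,
    up_thr: float = 1.1,
    down_thr: float = 0.9,
) -> tuple[list[io_mod.CandidateRecord], list[str]]:
    """Re-validate a ranked candidate table (report-only mode).

    Recomputes each row's pattern group from its normalised MASA and WD
    columns (second direction from norm_wd/norm_masa) and returns the records
    plus the genes whose printed group disagrees with the recomputation.
    Optionally rewrites the table to ``out_path``.
    """
    records = io_mod.read_candidate_table(candidates_path)
    mismatches = []
    for rec in records:
        recomputed = pat_mod.classify_pattern(
            rec.norm_masa, rec.norm_wd / rec.norm_masa, up_thr, down_thr
        )
        if recomputed is not rec.group:
            mismatches.append(rec.gene)
    if out_path is not None:
        io_mod.write_candidate_table(records, out_path)
    return records, mismatches
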