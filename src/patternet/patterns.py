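"""Three-timepoint expression-pattern classification.

Each gene is profiled at CON (baseline), MASA (after drug self-administration)
and WD (after withdrawal) in paired animals. The trajectory is summarised by
two fold-change ratios — MASA/CON and WD/MASA — each called up, constant or
down against fixed thresholds (default >1.1 / <0.9), and the ordered direction
pair assigns the gene to one of six pattern groups:

    G1 up-up     G2 up-down     G3 constant-up
    G4 constant-down   G5 down-up   G6 down-down

The three remaining direction pairs (second step constant) are not pattern
groups and map to NONE. A gene is only called patterned when every animal
shows the same group (unanimity consensus); a mean-ratio variant classifies
the rat-averaged ratios instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TIMEPOINTS, ExpressionMatrix
from .stats import one_way_anova

logger = logging.getLogger(__name__)

__all__ = [
    "PatternGroup",
    "RatioProfile",
    "anova_filter",
    "classify_direction",
    "classify_pattern",
    "classify_profiles",
    "compute_ratio_profiles",
    "consensus_pattern",
    "group_census",
]

UP_THRESHOLD = 1.1
DOWN_THRESHOLD = 0.9


class PatternGroup(str, Enum):
    """The six temporal pattern groups, plus NONE for unpatterned genes."""

    G1 = "G1"  # up, up
    G2 = "G2"  # up, down
    G3 = "G3"  # constant, up
    G4 = "G4"  # constant, down
    G5 = "G5"  # down, up
    G6 = "G6"  # down, down
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_GROUPS = tuple(g for g in PatternGroup if g is not PatternGroup.NONE)

_DIRECTION_MAP: dict[tuple[str, str], PatternGroup] = {
    ("up", "up"): PatternGroup.G1,
    ("up", "down"): PatternGroup.G2,
    ("constant", "up"): PatternGroup.G3,
    ("constant", "down"): PatternGroup.G4,
    ("down", "up"): PatternGroup.G5,
    ("down", "down"): PatternGroup.G6,
}


@dataclass(frozen=True)
class RatioProfile:
    """Per-gene fold-change summary.

    ``r1`` and ``r2`` hold the per-rat MASA/CON and WD/MASA ratios (same rat
    order); ``norm_masa`` and ``norm_wd`` are the rat means of MASA/CON and
    WD/CON — the two "normalised" columns a candidate report prints.
    """

    gene: str
    rats: tuple[int, ...]
    r1: tuple[float, ...]
    r2: tuple[float, ...]
    norm_masa: float
    norm_wd: float


def classify_direction(
    ratio: float, up_thr: float = UP_THRESHOLD, down_thr: float = DOWN_THRESHOLD
) -> str:
    """Call a fold-change ratio up/constant/down; boundaries are constant."""
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if not (up_thr > down_thr > 0):
        raise ValueError(f"need up_thr > down_thr > 0, got {up_thr}, {down_thr}")
    if ratio > up_thr:
        return "up"
    if ratio < down_thr:
        return "down"
    return "constant"


def classify_pattern(
    r1: float,
    r2: float,
    up_thr: float = UP_THRESHOLD,
    down_thr: float = DOWN_THRESHOLD,
) -> PatternGroup:
    """Map the (MASA/CON, WD/MASA) ratio pair to a pattern group."""
    d1 = classify_direction(r1, up_thr, down_thr)
    d2 = classify_direction(r2, up_thr, down_thr)
    return _DIRECTION_MAP.get((d1, d2), PatternGroup.NONE)


def consensus_pattern(per_rat_groups: Sequence[PatternGroup]) -> PatternGroup:
    """Unanimity consensus: the shared non-NONE group, else NONE."""
    if len(per_rat_groups) == 0:
        raise ValueError("consensus_pattern requires at least one per-rat group")
    first = per_rat_groups[0]
    if first is PatternGroup.NONE:
        return PatternGroup.NONE
    if all(g is first for g in per_rat_groups[1:]):
        return first
    return PatternGroup.NONE


def anova_filter(
    matrix: ExpressionMatrix, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Keep genes whose one-way ANOVA across the three timepoints has p < alpha.

    p-values are uncorrected. Genes with zero within-timepoint variance but
    unequal timepoint means get p = 0 (kept, logged); genes with all values
    identical get p = 1 (dropped).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    blocks = [matrix.timepoint(tp).to_numpy() for tp in TIMEPOINTS]
    pvals = {}
    degenerate = 0
    for i, gene in enumerate(matrix.genes):
        res = one_way_anova([b[i] for b in blocks])
        if res.method == "degenerate-zero":
            degenerate += 1
        pvals[gene] = res.p_value
    if degenerate:
        logger.info(
            "anova_filter: %d genes had zero within-timepoint variance with "
            "unequal means (p set to 0, retained)",
            degenerate,
        )
    pseries = pd.Series(pvals, name="anova_p")
    kept = [g for g in matrix.genes if pseries[g] < alpha]
    return kept, pseries


def compute_ratio_profiles(
    matrix: ExpressionMatrix,
    genes: Iterable[str] | None = None,
    pseudocount: float = 0.0,
) -> list[RatioProfile]:
    """Per-rat MASA/CON and WD/MASA ratios for the selected genes.

    With pseudocount 0 (default), genes with a zero abundance at any timepoint
    are excluded — a zero denominator or numerator has no defined direction.
    A positive pseudocount is added to every value instead.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    selected = list(genes) if genes is not None else list(matrix.genes)
    rats = matrix.rats
    con = matrix.timepoint("CON").loc[selected]
    masa = matrix.timepoint("MASA").loc[selected]
    wd = matrix.timepoint("WD").loc[selected]
    if pseudocount > 0:
        con, masa, wd = con + pseudocount, masa + pseudocount, wd + pseudocount
    ok = (con > 0).all(axis=1) & (masa > 0).all(axis=1) & (wd > 0).all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info(
            "compute_ratio_profiles: excluded %d genes with zero abundance", dropped
        )
    r1 = (masa / con)[ok]
    r2 = (wd / masa)[ok]
    nm = (masa / con)[ok].mean(axis=1)
    nw = (wd / con)[ok].mean(axis=1)
    return [
        RatioProfile(
            gene=g,
            rats=tuple(rats),
            r1=tuple(float(v) for v in r1.loc[g]),
            r2=tuple(float(v) for v in r2.loc[g]),
            norm_masa=float(nm.loc[g]),
            norm_wd=float(nw.loc[g]),
        )
        for g in r1.index
    ]


def classify_profiles(
    profiles: Iterable[RatioProfile],
    up_thr: float = UP_THRESHOLD,
    down_thr: float = DOWN_THRESHOLD,
    method: str = "consensus",
) -> dict[str, PatternGroup]:
    """Assign a pattern group to every profile.

    ``consensus`` (default) classifies each rat separately and requires
    unanimity; ``mean`` classifies the rat-mean ratios (norm_masa and
    norm_wd/norm_masa) directly.
    """
    if method not in ("consensus", "mean"):
        raise ValueError(f"unknown classification method {method!r}")
    out: dict[str, PatternGroup] = {}
    for prof in profiles:
        if method == "consensus":
            per_rat = [
                classify_pattern(a, b, up_thr, down_thr)
                for a, b in zip(prof.r1, prof.r2)
            ]
            out[prof.gene] = consensus_pattern(per_rat)
        else:
            out[prof.gene] = classify_pattern(
                prof.norm_masa, prof.norm_wd / prof.norm_masa, up_thr, down_thr
            )
    return out


def group_census(assignments: Mapping[str, PatternGroup]) -> dict[PatternGroup, int]:
    """Count genes per pattern group G1..G6 (NONE excluded)."""
    census = {g: 0 for g in _GROUPS}
    for grp in assignments.values():
        if grp is not PatternGroup.NONE:
            census[grp] += 1
    return census
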