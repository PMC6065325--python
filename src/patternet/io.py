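"""Readers and writers for the pipeline's flat-file formats.

Formats handled here:

* expression TSV — one gene-ID column plus one column per (timepoint, rat)
  sample named ``<TIMEPOINT>_<rat>`` with timepoints CON/MASA/WD;
* interaction links — whitespace-separated ``protein1 protein2 combined_score``
  with scores on the STRING 0-1000 confidence scale;
* curated gene lists — one symbol per line with an optional evidence-source
  tag (e.g. LT, mouse, human, HT);
* symbol-to-protein-ID mapping TSV;
* ranked candidate tables (the pipeline's final report).

Identifier normalisation is case-fold + strip throughout; no synonym
expansion is attempted beyond an optional explicit mapping table.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "ExpressionMatrix",
    "InteractionEdge",
    "CuratedGeneSet",
    "CandidateRecord",
    "normalize_symbol",
    "read_expression_table",
    "write_expression_table",
    "read_string_links",
    "write_string_links",
    "read_gene_set",
    "write_gene_set",
    "read_id_map",
    "read_candidate_table",
    "write_candidate_table",
]

TIMEPOINTS = ("CON", "MASA", "WD")

_SAMPLE_RE = re.compile(r"^(CON|MASA|WD)_(\d+)$")


def normalize_symbol(symbol: str) -> str:
    """Canonical identifier form used for all matching: strip + case-fold."""
    return symbol.strip().casefold()


class ExpressionMatrix:
    """Gene × (timepoint, rat) abundance matrix for a paired design.

    Wraps a DataFrame whose columns are a (timepoint, rat) MultiIndex; every
    rat must be present at all three timepoints, gene IDs must be unique and
    values nonnegative and finite.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 2:
            raise ValueError("expected (timepoint, rat) MultiIndex columns")
        tps = set(data.columns.get_level_values(0))
        if tps != set(TIMEPOINTS):
            raise ValueError(
                f"unbalanced design: need timepoints {TIMEPOINTS}, got {sorted(tps)}"
            )
        rat_sets = {
            tp: frozenset(data[tp].columns.astype(int)) for tp in TIMEPOINTS
        }
        if len(set(rat_sets.values())) != 1:
            raise ValueError(f"unbalanced design: rats per timepoint differ: {rat_sets}")
        dup = data.index[data.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene ID: {dup[0]}")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            gene = data.index[np.isnan(values).any(axis=1)][0]
            raise ValueError(f"missing value for gene {gene}")
        if (values < 0).any():
            gene = data.index[(values < 0).any(axis=1)][0]
            raise ValueError(f"negative abundance for gene {gene}")
        rats = sorted(rat_sets["CON"])
        cols = pd.MultiIndex.from_product([TIMEPOINTS, rats], names=["timepoint", "rat"])
        self._data = data.astype(float).reindex(columns=cols)
        self._rats = tuple(rats)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def genes(self) -> list[str]:
        return list(self._data.index)

    @property
    def rats(self) -> tuple[int, ...]:
        return self._rats

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def timepoint(self, tp: str) -> pd.DataFrame:
        """Genes × rats block for one timepoint (rat columns ascending)."""
        if tp not in TIMEPOINTS:
            raise KeyError(f"unknown timepoint {tp!r}")
        return self._data[tp]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._data.equals(other._data)


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a gene × sample TSV with ``<TIMEPOINT>_<rat>`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a gene column plus sample columns")
    gene_col = df.columns[0]
    tuples = []
    for col in df.columns[1:]:
        m = _SAMPLE_RE.match(str(col))
        if not m:
            raise ValueError(
                f"{path}: sample column {col!r} does not match <TIMEPOINT>_<rat>"
            )
        tuples.append((m.group(1), int(m.group(2))))
    dup_gene = df[gene_col][df[gene_col].duplicated()]
    if len(dup_gene):
        raise ValueError(f"{path}: duplicate gene ID: {dup_gene.iloc[0]}")
    data = df.set_index(gene_col)
    try:
        data = data.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric abundance value ({exc})") from exc
    data.columns = pd.MultiIndex.from_tuples(tuples, names=["timepoint", "rat"])
    return ExpressionMatrix(data)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix back to the flat TSV layout."""
    flat = matrix.data.copy()
    flat.columns = [f"{tp}_{rat}" for tp, rat in flat.columns]
    flat.index.name = "gene_id"
    flat.to_csv(path, sep="\t")


class InteractionEdge(NamedTuple):
    """One undirected scored link; node_a <= node_b after normalisation."""

    node_a: str
    node_b: str
    combined_score: int


def read_string_links(
    path: str | Path,
    score_min: int = 400,
    id_map: Mapping[str, str] | None = None,
) -> list[InteractionEdge]:
    """Read a STRING-style link table, returning undirected scored edges.

    Reciprocal duplicate rows collapse to one edge keeping the maximum score,
    self-pairs are dropped, and only edges with combined_score >= score_min
    survive (the conventional medium-confidence cutoff is 400, inclusive).
    An optional symbol mapping is applied to both endpoints before
    normalisation.
    """
    if not 0 <= score_min <= 1000:
        raise ValueError(f"score_min must be in [0, 1000], got {score_min}")
    best: dict[tuple[str, str], InteractionEdge] = {}
    with open(path) as fh:
        header = fh.readline().split()
        expected = ["protein1", "protein2", "combined_score"]
        if [h.casefold() for h in header[:3]] != expected:
            raise ValueError(f"{path}: expected header columns {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            a_raw, b_raw, score_raw = parts[0], parts[1], parts[2]
            try:
                score = int(score_raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer score at line {lineno}: {score_raw!r}"
                ) from exc
            if not 0 <= score <= 1000:
                raise ValueError(
                    f"{path}: score {score} outside [0, 1000] at line {lineno}"
                )
            if id_map is not None:
                a_raw = id_map.get(normalize_symbol(a_raw), a_raw)
                b_raw = id_map.get(normalize_symbol(b_raw), b_raw)
            na, nb = normalize_symbol(a_raw), normalize_symbol(b_raw)
            if na == nb:
                continue
            if nb < na:
                a_raw, b_raw = b_raw, a_raw
                na, nb = nb, na
            key = (na, nb)
            prev = best.get(key)
            if prev is None or score > prev.combined_score:
                best[key] = InteractionEdge(a_raw, b_raw, score)
    return sorted(
        (e for e in best.values() if e.combined_score >= score_min),
        key=lambda e: (normalize_symbol(e.node_a), normalize_symbol(e.node_b)),
    )


def write_string_links(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for e in edges:
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.combined_score}\n")


@dataclass(frozen=True)
class CuratedGeneSet:
    """A curated gene list with per-evidence-source counts.

    A symbol may carry several evidence sources, so source counts may sum to
    more than the number of unique symbols; they are only required to be
    nonnegative.
    """

    symbols: frozenset[str]
    source_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("curated gene set must not be empty")
        if any(v < 0 for v in self.source_counts.values()):
            raise ValueError("source counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols


def read_gene_set(path: str | Path) -> CuratedGeneSet:
    """Read a one-symbol-per-line gene list with optional evidence source."""
    symbols: set[str] = set()
    counts: Counter[str] = Counter()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            symbols.add(normalize_symbol(parts[0]))
            if len(parts) > 1:
                counts[parts[1]] += 1
    if not symbols:
        raise ValueError(f"{path}: empty curated gene set")
    return CuratedGeneSet(frozenset(symbols), dict(counts))


def write_gene_set(
    entries: Iterable[str | tuple[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for entry in entries:
            if isinstance(entry, str):
                fh.write(f"{entry}\n")
            else:
                fh.write(f"{entry[0]}\t{entry[1]}\n")


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column symbol → protein-ID TSV; keys are normalised symbols."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping table needs two columns")
    return {
        normalize_symbol(sym): str(pid)
        for sym, pid in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


@dataclass(frozen=True)
class CandidateRecord:
    """One row of the ranked candidate report."""

    rank: int
    gene: str
    bc: float
    curated: bool
    group: object  # PatternGroup; object here to keep io free of cycles
    norm_masa: float
    norm_wd: float


_CANDIDATE_COLUMNS = ["rank", "gene", "bc", "curated_flag", "group", "norm_masa", "norm_wd"]


def write_candidate_table(
    candidates: Sequence[CandidateRecord], path: str | Path
) -> None:
    """Write the ranked candidate report (BC printed to 4 decimals)."""
    ranks = [c.rank for c in candidates]
    if ranks != list(range(1, len(candidates) + 1)):
        raise ValueError(f"candidates must be ranked 1..n in order, got ranks {ranks}")
    with open(path, "w") as fh:
        fh.write("\t".join(_CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            group = c.group.value if hasattr(c.group, "value") else str(c.group)
            fh.write(
                f"{c.rank}\t{c.gene}\t{c.bc:.4f}\t{int(c.curated)}\t{group}"
                f"\t{c.norm_masa:.4f}\t{c.norm_wd:.4f}\n"
            )


def read_candidate_table(path: str | Path) -> list[CandidateRecord]:
    from .patterns import PatternGroup  # deferred: patterns imports this module

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: candidate table missing columns {missing}")
    return [
        CandidateRecord(
            rank=int(row["rank"]),
            gene=str(row["gene"]),
            bc=float(row["bc"]),
            curated=bool(int(row["curated_flag"])),
            group=PatternGroup(str(row["group"])),
            norm_masa=float(row["norm_masa"]),
            norm_wd=float(row["norm_wd"]),
        )
        for _, row in df.iterrows()
    ]
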