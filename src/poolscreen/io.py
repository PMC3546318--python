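"""Readers and writers for the tabular formats used throughout the toolkit.

All files are tab-delimited UTF-8 with a mandatory header line; lines
beginning with ``#`` are treated as comments and ignored.  The schemas are
deliberately minimal:

* probe table      — ``probe_id  green_1..green_n  red_1..red_n``
* annotation table — ``probe_id  shrna_id  gene_symbol``
* GO associations  — ``tax_id  gene_symbol  go_id  go_term``
* network edges    — ``gene_a  gene_b  [score]``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ProbeTable",
    "AnnotationMap",
    "GoMap",
    "SchemaError",
    "ParseError",
    "read_probe_table",
    "write_probe_table",
    "read_annotation",
    "write_annotation",
    "read_go_map",
    "read_network",
    "read_ratio_matrix",
    "write_ratio_matrix",
]


class SchemaError(ValueError):
    """A file's header does not declare the expected columns."""


class ParseError(ValueError):
    """A data cell could not be parsed; the message names the offending line."""


def _green_cols(n: int) -> list[str]:
    return [f"green_{j + 1}" for j in range(n)]


def _red_cols(n: int) -> list[str]:
    return [f"red_{j + 1}" for j in range(n)]


@dataclass
class ProbeTable:
    """Probe-level two-color signal table.

    ``frame`` holds one row per probe with columns ``probe_id``,
    ``green_1..green_n`` and ``red_1..red_n`` (arbitrary fluorescence
    units, non-negative).  ``rejected_lines`` records 1-based line numbers
    of input rows dropped because a signal cell was absent.
    """

    frame: pd.DataFrame
    n_replicates: int
    rejected_lines: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def probe_ids(self) -> pd.Series:
        return self.frame["probe_id"]

    @property
    def green(self) -> np.ndarray:
        return self.frame[_green_cols(self.n_replicates)].to_numpy(float)

    @property
    def red(self) -> np.ndarray:
        return self.frame[_red_cols(self.n_replicates)].to_numpy(float)

    def subset(self, mask: np.ndarray) -> "ProbeTable":
        return ProbeTable(self.frame.loc[mask].reset_index(drop=True), self.n_replicates)


@dataclass
class AnnotationMap:
    """Probe -> shRNA -> gene mapping.

    A probe listed under more than one shRNA sequence is flagged as
    multimapping; probes absent from the map are "unannotated" when joined
    against a probe table.  The mapping is nominally two probes per shRNA
    but any many-probes-to-one-shRNA layout is accepted.
    """

    probe_to_shrnas: dict[str, set[str]]
    shrna_to_gene: dict[str, str]

    def multimap(self, probe_id: str) -> bool:
        return len(self.probe_to_shrnas.get(probe_id, ())) > 1

    def status(self, probe_id: str) -> str:
        """One of ``annotated``, ``multimap``, ``unannotated`` (total join)."""
        shrnas = self.probe_to_shrnas.get(probe_id)
        if not shrnas:
            return "unannotated"
        return "multimap" if len(shrnas) > 1 else "annotated"

    def shrna_of(self, probe_id: str) -> str:
        shrnas = self.probe_to_shrnas.get(probe_id)
        if not shrnas or len(shrnas) != 1:
            raise KeyError(f"probe {probe_id!r} does not map to exactly one shRNA")
        return next(iter(shrnas))

    def probes_for(self, shrna_id: str) -> set[str]:
        return {p for p, s in self.probe_to_shrnas.items() if shrna_id in s}

    def gene_of(self, shrna_id: str) -> str | None:
        return self.shrna_to_gene.get(shrna_id)

    def __len__(self) -> int:
        return len(self.probe_to_shrnas)


@dataclass
class GoMap:
    """Gene -> set of GO identifiers, with term descriptions."""

    gene_to_terms: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())

    def genes_of(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if term in ts}

    @property
    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return out

    def __len__(self) -> int:
        return len(self.gene_to_terms)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_probe_table(path: str | Path, n_replicates: int = 6) -> ProbeTable:
    """Read a probe-level signal table.

    Raises :class:`SchemaError` if the header lacks ``probe_id`` or any of
    the ``green_j``/``red_j`` columns, and :class:`ParseError` naming the
    first offending line if a signal cell is non-numeric or negative.
    Rows with *empty* signal cells are rejected (the downstream intensity
    filter requires complete replicate sets) and reported by line number.
    """
    raw = _read_tsv(path)
    signal_cols = _green_cols(n_replicates) + _red_cols(n_replicates)
    missing = [c for c in ["probe_id", *signal_cols] if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    # header is line 1, data starts at line 2 (comment lines were stripped by
    # pandas, so line numbers are w.r.t. the comment-free file)
    lines = raw.index.to_numpy() + 2
    empty = (raw[signal_cols] == "").any(axis=1).to_numpy()
    probe = raw.loc[~empty, signal_cols].apply(pd.to_numeric, errors="coerce")
    bad = probe.isna().any(axis=1)
    if bad.any():
        first = probe.index[bad][0]
        raise ParseError(f"{path}: non-numeric signal value on line {first + 2}")
    # exact (round-trip) parse; pandas' fast float path can be off by 1 ulp
    numeric = raw.loc[~empty, signal_cols].astype(np.float64)
    if not np.isfinite(numeric.to_numpy(float)).all() or (numeric.to_numpy(float) < 0).any():
        raise ParseError(f"{path}: signals must be finite and non-negative")

    frame = raw.loc[~empty, ["probe_id"]].copy()
    frame[signal_cols] = numeric
    if frame["probe_id"].duplicated().any():
        dup = frame.loc[frame["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"{path}: duplicate probe_id {dup!r}")
    rejected = [int(x) for x in lines[empty]]
    if rejected:
        warnings.warn(f"{path}: rejected {len(rejected)} row(s) with missing signals")
    return ProbeTable(frame.reset_index(drop=True), n_replicates, rejected)


def write_probe_table(table: ProbeTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read a probe/shRNA/gene annotation table.

    Duplicate (probe, shRNA) rows are deduplicated with a warning.  A probe
    appearing under more than one distinct shRNA is retained but flagged as
    multimapping (such probes are removed by the preprocessing filter).
    """
    raw = _read_tsv(path)
    required = ["probe_id", "shrna_id"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "gene_symbol" not in raw.columns:
        raw["gene_symbol"] = ""

    dup = raw.duplicated(subset=["probe_id", "shrna_id"])
    if dup.any():
        warnings.warn(f"{path}: {int(dup.sum())} duplicate (probe, shRNA) row(s) ignored")
        raw = raw.loc[~dup]

    probe_to_shrnas: dict[str, set[str]] = {}
    shrna_to_gene: dict[str, str] = {}
    for probe, shrna, gene in raw[["probe_id", "shrna_id", "gene_symbol"]].itertuples(index=False):
        probe_to_shrnas.setdefault(probe, set()).add(shrna)
        if gene:
            shrna_to_gene.setdefault(shrna, gene)
    return AnnotationMap(probe_to_shrnas, shrna_to_gene)


def write_annotation(annotation: AnnotationMap, path: str | Path) -> None:
    rows = []
    for probe, shrnas in annotation.probe_to_shrnas.items():
        for shrna in sorted(shrnas):
            rows.append((probe, shrna, annotation.shrna_to_gene.get(shrna, "")))
    pd.DataFrame(rows, columns=["probe_id", "shrna_id", "gene_symbol"]).to_csv(
        path, sep="\t", index=False
    )


def read_go_map(path: str | Path, taxon: str | int = 10090) -> GoMap:
    """Read a gene2go-style association table, keeping one taxon only.

    The default taxon is mouse (10090).  Duplicate (gene, term) pairs —
    e.g. the same association under different evidence codes — collapse to
    a single association.  An empty result for the taxon is returned with a
    warning rather than an error.
    """
    raw = _read_tsv(path)
    required = ["tax_id", "gene_symbol", "go_id"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    kept = raw.loc[raw["tax_id"] == str(taxon)]
    if kept.empty:
        warnings.warn(f"{path}: no associations for taxon {taxon}")
    gene_to_terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for row in kept.itertuples(index=False):
        gene_to_terms.setdefault(row.gene_symbol, set()).add(row.go_id)
        if "go_term" in kept.columns and row.go_term:
            descriptions.setdefault(row.go_id, row.go_term)
    return GoMap(gene_to_terms, descriptions)


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected interaction network from an edge-per-line TSV.

    Duplicate edges (in either orientation) collapse keeping the maximum
    score; self-loops are dropped and counted in
    ``graph.graph["self_loops_dropped"]``.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise SchemaError(f"{path}: network file needs at least 2 columns")
    cols = list(raw.columns)
    has_score = len(cols) >= 3
    graph = nx.Graph()
    dropped = 0
    for row in raw.itertuples(index=False):
        a, b = row[0], row[1]
        if a == b:
            dropped += 1
            continue
        score = float(row[2]) if has_score and row[2] != "" else None
        if graph.has_edge(a, b):
            old = graph.edges[a, b].get("score")
            if score is not None and (old is None or score > old):
                graph.edges[a, b]["score"] = score
        else:
            graph.add_edge(a, b, **({"score": score} if score is not None else {}))
    graph.graph["self_loops_dropped"] = dropped
    return graph


def read_ratio_matrix(path: str | Path) -> pd.DataFrame:
    """Read a log-ratio matrix (rows: probe/shRNA ids, columns: rep_1..n)."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                        float_precision="round_trip")
    frame.index = frame.index.astype(str)
    return frame


def write_ratio_matrix(ratios: pd.DataFrame, path: str | Path) -> None:
    ratios.to_csv(path, sep="\t", index=True, index_label="id")
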