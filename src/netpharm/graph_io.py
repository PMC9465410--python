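"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain text: edge-list TSV for the interactome, GMT for gene
sets, labeled TSV for similarity matrices, TSV bitstrings for fingerprints,
CSV for meta-analysis study tables, and two-column TSV for ranked lists and
ortholog maps. Node identifiers are opaque strings; no ID-mapping logic lives
here — ortholog maps arrive as explicit two-column files.

Every reader/writer pair is a round-trip identity on valid objects, and
parsers never silently drop data: every discarded record is counted and
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netpharm")

__all__ = [
    "GeneSet",
    "BipartiteIncidence",
    "FingerprintSet",
    "RankedList",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "read_fingerprints",
    "write_fingerprints",
    "read_ranked_list",
    "write_ranked_list",
    "read_mapping",
    "write_mapping",
    "read_study_table",
    "write_study_table",
]


class ParseError(ValueError):
    """A malformed record in an input file; message carries the line number."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of node identifiers (drug targets, disease genes, a term)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class BipartiteIncidence:
    """0/1 incidence between two label universes (e.g. compound x target).

    Rows and columns keep their stated order; `values[i, j] == 1` means row
    label i is linked to column label j.
    """

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("incidence shape does not match labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("incidence cells must be 0/1")


@dataclass
class FingerprintSet:
    """Per-compound fixed-length bit vectors (structure fingerprints)."""

    bits: dict[str, np.ndarray]

    def __post_init__(self):
        lengths = {len(v) for v in self.bits.values()}
        if len(lengths) > 1:
            raise ValueError(f"fingerprint lengths differ: {sorted(lengths)}")
        if lengths and min(lengths) < 8:
            raise ValueError("fingerprints must have at least 8 bits")
        self.bits = {k: np.asarray(v, dtype=np.uint8) for k, v in self.bits.items()}

    @property
    def labels(self) -> list[str]:
        return list(self.bits)

    @property
    def n_bits(self) -> int:
        return len(next(iter(self.bits.values()))) if self.bits else 0

    def __getitem__(self, label: str) -> np.ndarray:
        return self.bits[label]

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class RankedList:
    """Genes ordered by score, descending; ties broken by gene name.

    The container enforces the strict ordering on construction so downstream
    enrichment walks a well-defined list.
    """

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        order = sorted(range(len(self.genes)), key=lambda i: (-self.scores[i], self.genes[i]))
        self.genes = [self.genes[i] for i in order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.genes)

    def rank_of(self, gene: str) -> int:
        return self.genes.index(gene)


@dataclass
class StudyTable:
    """Per-study arm summaries for meta-analysis.

    kind='continuous': columns study, n_e, mean_e, sd_e, n_c, mean_c, sd_c.
    kind='binary':     columns study, events_e, total_e, events_c, total_c.
    """

    kind: str
    records: pd.DataFrame

    CONTINUOUS_COLS = ["study", "n_e", "mean_e", "sd_e", "n_c", "mean_c", "sd_c"]
    BINARY_COLS = ["study", "events_e", "total_e", "events_c", "total_c"]

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown study table kind {self.kind!r}")
        cols = self.CONTINUOUS_COLS if self.kind == "continuous" else self.BINARY_COLS
        missing = set(cols) - set(self.records.columns)
        if missing:
            raise ValueError(f"study table missing columns: {sorted(missing)}")
        self.records = self.records[cols].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        for _, row in self.records.iterrows():
            label = row["study"]
            if self.kind == "continuous":
                if row["n_e"] < 1 or row["n_c"] < 1:
                    raise ValueError(f"study {label!r}: arm size < 1")
                if row["sd_e"] <= 0 or row["sd_c"] <= 0:
                    raise ValueError(f"study {label!r}: sd must be > 0")
            else:
                for arm in ("e", "c"):
                    ev, tot = row[f"events_{arm}"], row[f"total_{arm}"]
                    if not (0 <= ev <= tot):
                        raise ValueError(f"study {label!r}: events outside [0, total]")
                    if tot < 1:
                        raise ValueError(f"study {label!r}: arm total < 1")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# interactome edge lists


def read_edge_list(path) -> nx.Graph:
    """Parse a 2- or 3-column TSV edge list into an undirected weighted graph.

    Duplicate edges collapse keeping the max weight; self-loops are dropped
    (counted and logged). '#' lines are comments.
    """
    g = nx.Graph()
    n_self_loops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            a, b = parts[0].strip(), parts[1].strip()
            if not a or not b:
                raise ParseError(f"{path}:{lineno}: empty node identifier")
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            else:
                w = 1.0
            if w <= 0:
                raise ParseError(f"{path}:{lineno}: weight must be > 0")
            n_lines += 1
            if a == b:
                n_self_loops += 1
                continue
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self_loops)
    if g.number_of_edges() == 0:
        raise ParseError(f"{path}: no usable edges ({n_lines} records read)")
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):g}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, GeneSet]:
    """Read a GMT file (name, description, members..., tab-separated)."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if len(set(members)) != len(members):
                logger.warning("%s:%d: duplicate members in %r deduplicated", path, lineno, name)
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, frozenset(members), desc)
    return sets


def write_gmt(sets, path) -> None:
    if isinstance(sets, dict):
        sets = sets.values()
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# labeled matrices


def read_matrix(path, symmetric: bool = False) -> pd.DataFrame:
    """Read a labeled TSV matrix (header row, first-column labels)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    if symmetric:
        if list(m.index) != list(m.columns):
            raise ParseError(f"{path}: row and column labels differ")
        if not np.allclose(m.values, m.values.T, atol=1e-9):
            raise ParseError(f"{path}: matrix is not symmetric")
    return m


def write_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# fingerprints


def read_fingerprints(path) -> FingerprintSet:
    """TSV of (compound label, bitstring of 0/1 characters)."""
    bits: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected (label, bitstring)")
            label, bitstr = parts
            if set(bitstr) - {"0", "1"}:
                raise ParseError(f"{path}:{lineno}: bitstring has non-binary characters")
            if label in bits:
                raise ParseError(f"{path}:{lineno}: duplicate compound {label!r}")
            bits[label] = np.frombuffer(bitstr.encode(), dtype=np.uint8) - ord("0")
    return FingerprintSet(bits)


def write_fingerprints(fps: FingerprintSet, path) -> None:
    with open(path, "w") as fh:
        for label, vec in fps.bits.items():
            fh.write(f"{label}\t{''.join(str(int(b)) for b in vec)}\n")


# ---------------------------------------------------------------------------
# ranked lists and ortholog maps


def read_ranked_list(path) -> RankedList:
    """Two-column TSV (gene, score); sorted on load."""
    genes, scores = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected (gene, score)")
            genes.append(parts[0])
            try:
                scores.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {parts[1]!r}") from exc
    return RankedList(genes, np.array(scores))


def write_ranked_list(ranked: RankedList, path) -> None:
    with open(path, "w") as fh:
        for gene, score in zip(ranked.genes, ranked.scores):
            fh.write(f"{gene}\t{float(score)!r}\n")


def read_mapping(path) -> dict[str, list[str]]:
    """Two-column TSV source -> target; multi-mapped sources keep all targets."""
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected (source, target)")
            mapping.setdefault(parts[0], [])
            if parts[1] not in mapping[parts[0]]:
                mapping[parts[0]].append(parts[1])
    return mapping


def write_mapping(mapping: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for src, targets in mapping.items():
            for t in targets:
                fh.write(f"{src}\t{t}\n")


# ---------------------------------------------------------------------------
# meta-analysis study tables


def read_study_table(path) -> StudyTable:
    """Read a CSV study table; continuous vs binary auto-detected by header."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if set(StudyTable.CONTINUOUS_COLS) <= cols:
        kind = "continuous"
    elif set(StudyTable.BINARY_COLS) <= cols:
        kind = "binary"
    else:
        raise ParseError(
            f"{path}: header matches neither continuous {StudyTable.CONTINUOUS_COLS} "
            f"nor binary {StudyTable.BINARY_COLS} layout"
        )
    return StudyTable(kind, df)


def write_study_table(table: StudyTable, path) -> None:
    table.records.to_csv(path, index=False)
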