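"""Core data containers and text-based readers/writers.

Four artifact kinds flow through the pipeline:

* binary association tables (circRNA x disease, circRNA x GO term,
  circRNA x miRNA), read either as two-column edge lists or dense grids;
* circRNA nucleotide sequences (FASTA);
* a disease vocabulary DAG given as parent->child edges (MeSH-style);
* square similarity matrices, serialized as dense TSV with identifier
  headers.

Identifier matching everywhere is exact and case-sensitive after trimming
surrounding whitespace: silently case-folding ids such as
``hsa_circ_0067997`` could merge distinct entities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "SequenceSet",
    "DiseaseDAG",
    "SimilarityMatrix",
    "read_association_table",
    "write_association_table",
    "read_fasta",
    "write_fasta",
    "read_dag",
    "write_dag",
    "read_matrix",
    "write_matrix",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i).strip() for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")
    return ids


@dataclass
class AssociationMatrix:
    """Binary association table: rows are circRNAs, columns a second entity.

    The column entity is diseases for the main table, GO terms or miRNAs
    for the annotation tables.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("association matrix must be 2-dimensional")
        if not np.isin(self.values, (0, 1)).all():
            bad = self.values[~np.isin(self.values, (0, 1))].flat[0]
            raise FormatError(f"association matrix entries must be 0/1, found {bad!r}")
        self.values = self.values.astype(np.int8)
        self.row_ids = _check_unique(self.row_ids, "row")
        self.col_ids = _check_unique(self.col_ids, "column")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} column ids"
            )
        if self.values.sum() == 0:
            raise ValidationError("association matrix has no associations at all")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def col_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.col_ids)}


@dataclass
class SequenceSet:
    """Nucleotide sequences keyed by circRNA identifier (uppercase)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for cid, seq in self.sequences.items():
            cid = str(cid).strip()
            seq = str(seq).strip().upper()
            if not seq:
                raise ValidationError(f"empty sequence for {cid!r}")
            clean[cid] = seq
        self.sequences = clean

    def __contains__(self, cid: str) -> bool:
        return cid in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def coverage(self, ids: Iterable[str]) -> list[str]:
        """The subset of *ids* that have a sequence, in the given order."""
        return [i for i in ids if i in self.sequences]


@dataclass
class DiseaseDAG:
    """Directed acyclic graph of disease terms, edges parent -> child.

    Multiple parents are allowed (MeSH terms can sit under several
    branches).  Diseases absent from the DAG are simply not covered; the
    fusion stage falls back to the interaction-profile kernel for them.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise ValidationError(f"disease graph contains a cycle: {path}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "DiseaseDAG":
        g = nx.DiGraph()
        g.add_nodes_from(str(n).strip() for n in nodes)
        g.add_edges_from((str(u).strip(), str(v).strip()) for u, v in edges)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def __contains__(self, disease: str) -> bool:
        return disease in self.graph

    def covered(self, ids: Iterable[str]) -> list[str]:
        """The subset of *ids* present in the DAG, in the given order."""
        return [d for d in ids if d in self.graph]

    def ancestor_set(self, disease: str) -> set[str]:
        """The disease itself plus every term reachable against the edges."""
        return {disease} | nx.ancestors(self.graph, disease)


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of pairwise scores with an identifier list."""

    values: np.ndarray
    ids: list[str]
    name: str = field(default="", compare=False)

    _SYM_TOL = 1e-9

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = _check_unique(self.ids, "similarity")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"similarity matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("similarity matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=self._SYM_TOL, rtol=0.0):
            raise ValidationError("similarity matrix is not symmetric within 1e-9")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], list(ids), self.name)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_association_table(path: str | Path, format: str = "edge_list") -> AssociationMatrix:
    """Load a binary association table.

    ``edge_list`` rows are ``row_id <TAB> col_id`` (an optional third weight
    column is ignored; duplicate edges collapse to a single 1).  ``dense``
    is a TSV grid with a header row of column ids and a first column of row
    ids; every cell must be exactly 0 or 1.
    """
    path = Path(path)
    if format == "edge_list":
        rows: list[str] = []
        cols: list[str] = []
        edges: set[tuple[str, str]] = set()
        seen_r: set[str] = set()
        seen_c: set[str] = set()
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: edge list rows need at least two columns"
                    )
                r, c = parts[0].strip(), parts[1].strip()
                if r not in seen_r:
                    seen_r.add(r)
                    rows.append(r)
                if c not in seen_c:
                    seen_c.add(c)
                    cols.append(c)
                edges.add((r, c))
        if not edges:
            raise ValidationError(f"{path}: empty association table")
        values = np.zeros((len(rows), len(cols)), dtype=np.int8)
        ridx = {r: i for i, r in enumerate(rows)}
        cidx = {c: i for i, c in enumerate(cols)}
        for r, c in edges:
            values[ridx[r], cidx[c]] = 1
        return AssociationMatrix(values, rows, cols)
    if format == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        raw = df.to_numpy()
        if raw.size and not np.isin(raw, (0, 1)).all():
            bad = raw[~np.isin(raw, (0, 1))].flat[0]
            raise FormatError(f"{path}: non-binary entry {bad!r} in dense table")
        return AssociationMatrix(
            raw, [str(i) for i in df.index], [str(c) for c in df.columns]
        )
    raise FormatError(f"unknown association table format {format!r}")


def write_association_table(
    m: AssociationMatrix, path: str | Path, format: str = "edge_list"
) -> None:
    path = Path(path)
    if format == "edge_list":
        with path.open("w") as fh:
            for i, r in enumerate(m.row_ids):
                for j in np.flatnonzero(m.values[i]):
                    fh.write(f"{r}\t{m.col_ids[j]}\n")
    elif format == "dense":
        pd.DataFrame(m.values, index=m.row_ids, columns=m.col_ids).to_csv(path, sep="\t")
    else:
        raise FormatError(f"unknown association table format {format!r}")


def read_fasta(path: str | Path, known_ids: Iterable[str]) -> SequenceSet:
    """Load circRNA sequences, keeping only records whose first header token
    is a known circRNA identifier.  Unknown records are dropped with a
    warning; sequences are uppercased."""
    known = set(str(i).strip() for i in known_ids)
    sequences: dict[str, str] = {}
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        cid = rec.id.strip()
        seq = str(rec.seq).strip().upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for record {cid!r}")
        if cid not in known:
            dropped += 1
            continue
        sequences[cid] = seq
    if dropped:
        logger.warning("%s: dropped %d FASTA records with unknown ids", path, dropped)
    return SequenceSet(sequences)


def write_fasta(seqs: SequenceSet | Mapping[str, str], path: str | Path, width: int = 70) -> None:
    data = seqs.sequences if isinstance(seqs, SequenceSet) else seqs
    with Path(path).open("w") as fh:
        for cid, seq in data.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_dag(path: str | Path) -> DiseaseDAG:
    """Load the disease DAG from a TSV of ``parent <TAB> child`` rows.

    Single-column rows declare isolated nodes, so diseases with a MeSH
    entry but no stated parents still count as covered.
    """
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split("\t") if p.strip()]
            if len(parts) == 1:
                nodes.append(parts[0])
            elif len(parts) == 2:
                edges.append((parts[0], parts[1]))
            else:
                raise FormatError(f"{path}:{lineno}: expected 1 or 2 columns")
    return DiseaseDAG.from_edges(edges, nodes)


def write_dag(dag: DiseaseDAG, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        isolated = dag.nodes - {u for u, _ in dag.edges} - {v for _, v in dag.edges}
        for u, v in dag.edges:
            fh.write(f"{u}\t{v}\n")
        for n in sorted(isolated):
            fh.write(f"{n}\n")


def write_matrix(m: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as dense TSV with id headers, at full
    float precision so a read back is bit-equal."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["id"] + m.ids) + "\n")
        for i, rid in enumerate(m.ids):
            row = "\t".join(repr(float(v)) for v in m.values[i])
            fh.write(f"{rid}\t{row}\n")


def read_matrix(path: str | Path, name: str = "") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return SimilarityMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index], name)
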