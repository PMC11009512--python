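"""Readers and writers for the package's text formats.

All inputs are plain text: FASTA for miRNA sequences, two-column delimited
files for every pairwise association list, a child->parent edge list plus a
disease->term map for the disease ontology, and headered delimited matrices
for serialized similarity/adjacency matrices.  Parsers are pure functions of
the file bytes; matrices round-trip bit-exactly at the chosen text precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Entity roles a column of an edge list may carry.
ROLES = ("miRNA", "disease", "drug", "mRNA", "lncRNA")

_RNA_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class SequenceRecord:
    """A single RNA sequence keyed by an opaque identifier.

    Sequences are stored uppercase over {A, C, G, U}; DNA-style input is
    accepted on read by mapping T to U.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c in bad
            )
            raise ValueError(
                f"sequence for {self.id!r} contains invalid character "
                f"{self.sequence[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EdgeList:
    """A typed bipartite edge list.

    The roles of the two columns are declared by the caller, never inferred
    from file content.  Pairs are unique after duplicate collapse and keep
    first-occurrence order.
    """

    source_type: str
    target_type: str
    pairs: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        for role in (self.source_type, self.target_type):
            if role not in ROLES:
                raise ValueError(f"unknown entity role {role!r}; expected one of {ROLES}")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs after canonicalization")

    def __len__(self) -> int:
        return len(self.pairs)

    def sources(self) -> List[str]:
        return sorted({s for s, _ in self.pairs})

    def targets(self) -> List[str]:
        return sorted({t for _, t in self.pairs})


@dataclass(frozen=True)
class DagEdges:
    """A disease ontology: child->parent term edges plus a disease->terms map.

    The edge set must be acyclic (MeSH-style descriptor hierarchy flattened to
    an edge list); every disease must map to at least one term present in the
    DAG.  Terms unreachable from any disease are retained.
    """

    edges: Tuple[Tuple[str, str], ...]
    term_of_disease: Dict[str, frozenset]
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"term hierarchy contains a cycle: {cycle}")
        known = set(g.nodes)
        for disease, terms in self.term_of_disease.items():
            if not terms:
                raise ValueError(f"disease {disease!r} maps to no terms")
            missing = set(terms) - known
            if missing:
                # a term with no edges is legal if it is its own root
                g.add_nodes_from(missing)
        object.__setattr__(self, "_graph", g)

    @property
    def graph(self) -> nx.DiGraph:
        """child->parent term graph (a DAG)."""
        return self._graph

    def ancestors_closure(self, terms: Sequence[str]) -> Set[str]:
        """Terms plus all their ancestors — the node set D(A) of a disease DAG."""
        out: Set[str] = set()
        for t in terms:
            if t not in self._graph:
                raise KeyError(f"term {t!r} absent from the DAG")
            out.add(t)
            out |= nx.descendants(self._graph, t)  # edges run child->parent
        return out


def read_fasta(path: str | Path) -> List[SequenceRecord]:
    """Read RNA (or DNA-style) FASTA into :class:`SequenceRecord` objects.

    Sequences are uppercased and T is mapped to U; ids must be unique within
    the file and characters outside {A,C,G,U,T} are rejected with the
    offending position named.
    """
    records: List[SequenceRecord] = []
    seen: Set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("T", "U")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_edge_list(
    path: str | Path,
    source_type: str,
    target_type: str,
    delimiter: str = "\t",
) -> EdgeList:
    """Read a two-column delimited association file.

    Duplicate rows are collapsed (first occurrence wins the ordering); a row
    with a field count other than 2 raises with its line number.  A header
    row is detected only when its two fields literally equal the declared
    roles.
    """
    pairs: List[Tuple[str, str]] = []
    seen: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            pair = (fields[0].strip(), fields[1].strip())
            if lineno == 1 and pair == (source_type, target_type):
                continue  # header
            if pair in seen:
                continue
            seen.add(pair)
            pairs.append(pair)
    logger.info("read %d unique %s-%s pairs from %s", len(pairs), source_type, target_type, path)
    return EdgeList(source_type, target_type, tuple(pairs))


def write_edge_list(edges: EdgeList, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for s, t in edges.pairs:
            fh.write(f"{s}{delimiter}{t}\n")


def read_dag(
    path: str | Path,
    term_map_path: str | Path,
    delimiter: str = "\t",
) -> DagEdges:
    """Read a child->parent term edge list and a (disease, term) map.

    Acyclicity is verified on construction; a disease with no terms is an
    error.
    """
    edge_rows = read_edge_list(path, "disease", "disease", delimiter=delimiter).pairs
    term_map: Dict[str, set] = {}
    with open(term_map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) != 2:
                raise ValueError(
                    f"{term_map_path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            term_map.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return DagEdges(tuple(edge_rows), {d: frozenset(ts) for d, ts in term_map.items()})


def write_dag(dag: DagEdges, path: str | Path, term_map_path: str | Path,
              delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for child, parent in dag.edges:
            fh.write(f"{child}{delimiter}{parent}\n")
    with open(term_map_path, "w") as fh:
        for disease in sorted(dag.term_of_disease):
            for term in sorted(dag.term_of_disease[disease]):
                fh.write(f"{disease}{delimiter}{term}\n")


def write_matrix(
    values: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
    float_format: str = "%.17g",
) -> None:
    """Serialize a matrix as headered TSV; %.17g round-trips float64 exactly."""
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", float_format=float_format)


def read_matrix(path: str | Path) -> tuple[np.ndarray, List[str], List[str]]:
    """Read a matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
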