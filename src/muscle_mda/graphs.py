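"""Heterogeneous view graphs linking miRNAs and diseases through mediators.

Each view couples the two target entity classes through one mediator class:
drugs (MDD), mRNAs (MMD) or lncRNAs (MLD).  A view's adjacency is binary and
symmetric over a fixed block layout — miRNA block, mediator block(s),
disease block, each sorted lexicographically — and NEVER contains a direct
miRNA-disease edge: the supervised signal reaches the model only through
labels, so the graphs cannot leak test associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .io_formats import EdgeList

logger = logging.getLogger(__name__)

#: view tag -> mediator role
VIEW_MEDIATORS = {"MDD": "drug", "MMD": "mRNA", "MLD": "lncRNA"}


@dataclass(frozen=True)
class EntityIndex:
    """Stable id->row mapping with block structure miRNA | mediators | disease.

    ``mediators`` maps mediator role -> ordered id list; blocks are laid out
    in the order miRNA, mediator roles as given, disease.  miRNA and disease
    orderings are shared across views so embedding rows align.
    """

    mirnas: Tuple[str, ...]
    diseases: Tuple[str, ...]
    mediators: Dict[str, Tuple[str, ...]]

    def __post_init__(self) -> None:
        blocks = [self.mirnas, self.diseases, *self.mediators.values()]
        all_ids = [i for b in blocks for i in b]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("entity blocks overlap or contain duplicates")

    @classmethod
    def build(
        cls,
        mirnas: Sequence[str],
        diseases: Sequence[str],
        mediators: Dict[str, Sequence[str]],
    ) -> "EntityIndex":
        return cls(
            tuple(sorted(mirnas)),
            tuple(sorted(diseases)),
            {role: tuple(sorted(ids)) for role, ids in mediators.items()},
        )

    @property
    def n_mirna(self) -> int:
        return len(self.mirnas)

    @property
    def n_disease(self) -> int:
        return len(self.diseases)

    @property
    def n_nodes(self) -> int:
        return self.n_mirna + sum(len(v) for v in self.mediators.values()) + self.n_disease

    def offsets(self) -> Dict[str, int]:
        """Block start offsets in node order miRNA, mediators, disease."""
        out = {"miRNA": 0}
        pos = self.n_mirna
        for role, ids in self.mediators.items():
            out[role] = pos
            pos += len(ids)
        out["disease"] = pos
        return out

    def position(self, role: str, entity: str) -> int:
        """Row of ``entity`` (of class ``role``) in the stacked node order."""
        off = self.offsets()
        if role == "miRNA":
            block: Sequence[str] = self.mirnas
        elif role == "disease":
            block = self.diseases
        else:
            block = self.mediators[role]
        try:
            return off[role] + block.index(entity)
        except ValueError:
            raise KeyError(f"{role} id {entity!r} not in index") from None

    def node_ids(self) -> List[str]:
        out = list(self.mirnas)
        for ids in self.mediators.values():
            out.extend(ids)
        out.extend(self.diseases)
        return out


@dataclass(frozen=True)
class ViewAdjacency:
    """One view's binary symmetric adjacency with its entity index."""

    view: str
    index: EntityIndex
    A: np.ndarray

    def __post_init__(self) -> None:
        n = self.index.n_nodes
        if self.A.shape != (n, n):
            raise ValueError(f"{self.view}: adjacency shape {self.A.shape}, expected ({n},{n})")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError(f"{self.view}: adjacency not symmetric")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError(f"{self.view}: adjacency not binary")
        if np.diag(self.A).any():
            raise ValueError(f"{self.view}: nonzero diagonal")
        off = self.index.offsets()
        m0, m1 = off["miRNA"], off["miRNA"] + self.index.n_mirna
        d0 = off["disease"]
        if self.A[m0:m1, d0 : d0 + self.index.n_disease].any():
            raise ValueError(f"{self.view}: direct miRNA-disease edge present (label leakage)")

    @property
    def n_nodes(self) -> int:
        return self.index.n_nodes


def _add_edges(
    A: np.ndarray,
    edges: EdgeList,
    index: EntityIndex,
) -> int:
    """Symmetrically set adjacency entries; returns the number of dropped
    direct miRNA-disease pairs."""
    roles = {edges.source_type, edges.target_type}
    dropped = 0
    for s, t in edges.pairs:
        if roles == {"miRNA", "disease"}:
            dropped += 1
            continue
        i = index.position(edges.source_type, s)
        j = index.position(edges.target_type, t)
        A[i, j] = A[j, i] = 1
    if dropped:
        logger.warning("dropped %d direct miRNA-disease pairs from the view graph", dropped)
    return dropped


def build_view(
    edges_m_x: EdgeList,
    edges_x_d: EdgeList,
    view: str,
    index: EntityIndex,
) -> ViewAdjacency:
    """Assemble one mediated view from miRNA-mediator and mediator-disease edges.

    Any direct miRNA-disease pair supplied by mistake is dropped with a
    warning; isolated nodes are retained; the result is symmetric, binary and
    has an identically zero miRNA x disease block.
    """
    if view not in VIEW_MEDIATORS:
        raise ValueError(f"unknown view {view!r}; expected one of {sorted(VIEW_MEDIATORS)}")
    mediator = VIEW_MEDIATORS[view]
    expect = [{"miRNA", mediator}, {mediator, "disease"}]
    got = [{edges_m_x.source_type, edges_m_x.target_type},
           {edges_x_d.source_type, edges_x_d.target_type}]
    if got != expect:
        raise ValueError(f"{view}: edge roles {got} do not match expected {expect}")
    A = np.zeros((index.n_nodes, index.n_nodes), dtype=np.int8)
    _add_edges(A, edges_m_x, index)
    _add_edges(A, edges_x_d, index)
    return ViewAdjacency(view, index, A)


def build_single_hetero_graph(
    edge_lists: Sequence[EdgeList],
    index: EntityIndex,
) -> ViewAdjacency:
    """Union all mediated edges into one single-heterogeneous-graph adjacency.

    Used by the SHG comparison mode: every entity class lives in one block
    structure and the result is the elementwise OR of the per-view matrices
    embedded in it.  Direct miRNA-disease pairs are still excluded.
    """
    A = np.zeros((index.n_nodes, index.n_nodes), dtype=np.int8)
    for edges in edge_lists:
        _add_edges(A, edges, index)
    return ViewAdjacency("SHG", index, A)
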