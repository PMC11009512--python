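"""Prior attribute features for miRNAs and diseases.

Three sources of prior knowledge are engineered into feature matrices:

* sequence composition — sliding-window k-mer frequency profiles of the
  miRNA sequences (default k=3, a 64-dimensional simplex vector per miRNA);
* disease ontology semantics — two Wang-style semantic similarities over the
  MeSH-like descriptor DAG: DSS1 from exponentially decayed term
  contributions and DSS2 from information-content-like term weights
  (-log of the fraction of disease DAGs containing the term);
* interaction topology — Gaussian interaction profile (GIP) kernels over the
  binary miRNA-disease association matrix, bandwidth normalized by the mean
  squared profile norm.

The integrated matrices are DM (k-mer profile concatenated with the miRNA
GIP row) and DD (mean of DSS1 and DSS2 where both diseases carry ontology
terms, GIP similarity otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io_formats import DagEdges, SequenceRecord

_BASES = "ACGU"

_UNIT_DIAG_ROLES = {"DSS1", "KD", "KM"}


def kmer_vocabulary(k: int) -> List[str]:
    """All 4^k k-mers over (A, C, G, U) in lexicographic order."""
    return ["".join(p) for p in product(_BASES, repeat=k)]


@dataclass(frozen=True)
class KmerProfile:
    """Normalized k-mer frequency vector of one sequence."""

    id: str
    k: int
    vector: np.ndarray

    def __post_init__(self) -> None:
        if self.vector.shape != (4 ** self.k,):
            raise ValueError(
                f"profile for {self.id!r} has length {self.vector.shape}, expected {4 ** self.k}"
            )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix with a role tag and row/col ids."""

    role: str
    ids: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"{self.role}: shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError(f"{self.role}: matrix is not symmetric")
        if self.role in _UNIT_DIAG_ROLES and not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError(f"{self.role}: diagonal is not 1")


@dataclass(frozen=True)
class AttributeMatrix:
    """Per-entity attribute feature rows (not necessarily square), e.g. DM."""

    role: str
    ids: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.ids):
            raise ValueError(f"{self.role}: {self.values.shape[0]} rows for {len(self.ids)} ids")

    @property
    def width(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# sequence features


def kmer_profile(record: SequenceRecord, k: int = 3) -> KmerProfile:
    """Sliding-window k-mer frequency profile, normalized to sum to 1.

    A sequence of length m yields m-k+1 windows; counts are divided by the
    window count, so the vector lies on the 4^k simplex.
    """
    m = len(record.sequence)
    if m < k:
        raise ValueError(f"sequence {record.id!r} shorter than k={k} (length {m})")
    index = {kmer: i for i, kmer in enumerate(kmer_vocabulary(k))}
    counts = np.zeros(4 ** k)
    for i in range(m - k + 1):
        counts[index[record.sequence[i : i + k]]] += 1
    return KmerProfile(record.id, k, counts / (m - k + 1))


def kmer_matrix(records: Sequence[SequenceRecord], k: int = 3) -> AttributeMatrix:
    """Stack k-mer profiles into the sequence attribute matrix SM."""
    rows = [kmer_profile(r, k).vector for r in records]
    return AttributeMatrix("SM", tuple(r.id for r in records), np.vstack(rows))


# ---------------------------------------------------------------------------
# disease semantic similarity


def semantic_contribution(
    dag: DagEdges, disease: str, delta: float = 0.5
) -> Dict[str, float]:
    """Decayed contribution D_A(t) of every term t in the disease's DAG.

    The disease's own descriptor terms contribute 1; an ancestor term
    contributes delta times the largest contribution among its children
    inside the disease's DAG (max over paths of delta^path_length).
    """
    if not 0 < delta <= 1:
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    base_terms = dag.term_of_disease.get(disease)
    if base_terms is None:
        raise KeyError(f"disease {disease!r} has no ontology terms")
    nodes = dag.ancestors_closure(sorted(base_terms))
    sub = dag.graph.subgraph(nodes)  # edges child -> parent
    contrib: Dict[str, float] = {}
    for term in nx.topological_sort(sub):  # children before parents
        if term in base_terms:
            contrib[term] = 1.0
        else:
            children = [c for c, _ in sub.in_edges(term)]
            contrib[term] = delta * max(contrib[c] for c in children)
    return contrib


def semantic_value(contrib: Mapping[str, float]) -> float:
    """DV(A): total semantic value, the sum of all term contributions.

    Summed in sorted term order so the float result is independent of dict
    iteration order (and hence of the interpreter's hash seed).
    """
    return float(sum(contrib[t] for t in sorted(contrib)))


def dss1(contrib_a: Mapping[str, float], contrib_b: Mapping[str, float]) -> float:
    """Decay-based semantic similarity of two diseases.

    Shared-term contributions from both DAGs, normalized by the two semantic
    values; equals 1 for identical DAGs and 0 for disjoint ones.
    """
    shared = sorted(contrib_a.keys() & contrib_b.keys())
    num = sum(contrib_a[t] + contrib_b[t] for t in shared)
    den = semantic_value(contrib_a) + semantic_value(contrib_b)
    return float(np.clip(num / den, 0.0, 1.0))


def d2_contribution(
    dag_membership: Mapping[str, int], term: str, n_diseases: int
) -> float:
    """Frequency-weighted term contribution: -ln(#DAGs containing t / #diseases).

    ``dag_membership`` maps each term to the number of disease DAGs whose
    node set contains it.
    """
    count = dag_membership.get(term, 0)
    if count < 1:
        raise ValueError(f"term {term!r} appears in no disease DAG")
    return float(-np.log(count / n_diseases))


def dss2(
    contrib2_a: Mapping[str, float],
    contrib2_b: Mapping[str, float],
    dv_a: float,
    dv_b: float,
    clip: bool = True,
) -> float:
    """Frequency-weighted semantic similarity over shared DAG terms.

    Numerator sums the information-content-like weights of shared terms;
    the denominator reuses the decay-based semantic values DV.  The ratio is
    nonnegative and may exceed 1; by default it is clipped to [0, 1].
    """
    shared = sorted(contrib2_a.keys() & contrib2_b.keys())
    num = sum(contrib2_a[t] + contrib2_b[t] for t in shared)
    val = num / (dv_a + dv_b)
    if clip:
        val = float(np.clip(val, 0.0, 1.0))
    return float(val)


def semantic_similarity_matrices(
    dag: DagEdges,
    diseases: Sequence[str],
    delta: float = 0.5,
    clip: bool = True,
) -> tuple[SimilarityMatrix, SimilarityMatrix, np.ndarray]:
    """DSS1 and DSS2 over a disease list, plus the has-terms mask.

    Diseases absent from the ontology term map get zero rows/columns in both
    matrices and ``False`` in the returned mask; the integration step falls
    back to the GIP kernel for those pairs.  DSS1 diagonal is forced to 1
    for masked diseases.
    """
    n = len(diseases)
    mask = np.array([d in dag.term_of_disease for d in diseases])
    contribs: Dict[str, Dict[str, float]] = {
        d: semantic_contribution(dag, d, delta) for d, m in zip(diseases, mask) if m
    }
    dvs = {d: semantic_value(c) for d, c in contribs.items()}
    membership: Dict[str, int] = {}
    for c in contribs.values():
        for t in c:
            membership[t] = membership.get(t, 0) + 1
    contribs2 = {
        d: {t: d2_contribution(membership, t, n) for t in c}
        for d, c in contribs.items()
    }
    m1 = np.zeros((n, n))
    m2 = np.zeros((n, n))
    for i, di in enumerate(diseases):
        if not mask[i]:
            continue
        m1[i, i] = 1.0
        m2[i, i] = dss2(contribs2[di], contribs2[di], dvs[di], dvs[di], clip=clip)
        for j in range(i + 1, n):
            dj = diseases[j]
            if not mask[j]:
                continue
            m1[i, j] = m1[j, i] = dss1(contribs[di], contribs[dj])
            m2[i, j] = m2[j, i] = dss2(
                contribs2[di], contribs2[dj], dvs[di], dvs[dj], clip=clip
            )
    # unmasked diseases: keep a unit self-similarity so DSS1 stays a valid
    # similarity matrix even when the ontology does not cover every disease
    for i in range(n):
        if not mask[i]:
            m1[i, i] = 1.0
    return (
        SimilarityMatrix("DSS1", tuple(diseases), m1),
        SimilarityMatrix("DSS2", tuple(diseases), m2),
        mask,
    )


# ---------------------------------------------------------------------------
# GIP kernel


def gip_kernel(
    profiles: np.ndarray, ids: Sequence[str], role: str, gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over binary association rows.

    K(i, j) = exp(-gamma * ||G(i) - G(j)||^2) with the bandwidth gamma =
    gamma_prime divided by the mean squared row norm over all n rows.
    """
    G = np.asarray(profiles, dtype=float)
    if not np.isin(G, (0.0, 1.0)).all():
        raise ValueError("interaction profiles must be binary")
    if gamma_prime <= 0:
        raise ValueError(f"gamma_prime must be positive, got {gamma_prime}")
    mean_norm = float((G ** 2).sum(axis=1).mean())
    if mean_norm == 0.0:
        raise ValueError("all-zero interaction profile matrix: GIP bandwidth undefined")
    gamma = gamma_prime / mean_norm
    sq = squareform(pdist(G, metric="sqeuclidean"))
    return SimilarityMatrix(role, tuple(ids), np.exp(-gamma * sq))


# ---------------------------------------------------------------------------
# integration


def integrate_mirna(sm: AttributeMatrix, km: SimilarityMatrix) -> AttributeMatrix:
    """Concatenate sequence (SM) and GIP (KM) rows into the miRNA matrix DM."""
    if sm.ids != km.ids:
        raise ValueError("SM and KM row orders disagree")
    return AttributeMatrix("DM", sm.ids, np.hstack([sm.values, km.values]))


def integrate_disease(
    dss1_m: SimilarityMatrix,
    dss2_m: SimilarityMatrix,
    kd: SimilarityMatrix,
    semantic_mask: np.ndarray,
) -> SimilarityMatrix:
    """Blend semantic and GIP similarity into the disease matrix DD.

    A pair whose two diseases both carry ontology terms gets the mean of
    DSS1 and DSS2; any other pair falls back to the GIP value KD.
    """
    if not (dss1_m.ids == dss2_m.ids == kd.ids):
        raise ValueError("DSS1/DSS2/KD row orders disagree")
    pair_mask = np.outer(semantic_mask, semantic_mask)
    dd = np.where(pair_mask, (dss1_m.values + dss2_m.values) / 2.0, kd.values)
    return SimilarityMatrix("DD", kd.ids, dd)
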