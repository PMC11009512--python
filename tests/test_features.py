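"""Attribute feature engines: k-mer profiles, semantic similarity, GIP, integration."""

import itertools

import networkx as nx
import numpy as np
import pytest

from muscle_mda.features import (
    AttributeMatrix,
    SimilarityMatrix,
    d2_contribution,
    dss1,
    dss2,
    gip_kernel,
    integrate_disease,
    integrate_mirna,
    kmer_matrix,
    kmer_profile,
    kmer_vocabulary,
    semantic_contribution,
    semantic_similarity_matrices,
    semantic_value,
)
from muscle_mda.io_formats import DagEdges, SequenceRecord


class TestKmerProfile:
    def test_vocabulary_size(self):
        assert len(kmer_vocabulary(3)) == 64
        assert kmer_vocabulary(1) == ["A", "C", "G", "U"]

    def test_uniform_sequence_concentrates(self):
        prof = kmer_profile(SequenceRecord("m", "AAAA"), k=3)
        assert prof.vector[0] == 1.0  # AAA is lexicographically first
        assert prof.vector.sum() == 1.0

    def test_two_window_sequence(self):
        prof = kmer_profile(SequenceRecord("m", "ACGU"), k=3)
        vocab = kmer_vocabulary(3)
        assert prof.vector[vocab.index("ACG")] == 0.5
        assert prof.vector[vocab.index("CGU")] == 0.5
        assert prof.vector.sum() == 1.0

    def test_window_count_for_22nt(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=22))
        prof = kmer_profile(SequenceRecord("m", seq), k=3)
        # m - k + 1 sliding windows; counts normalized by exactly that number
        counts = prof.vector * (22 - 3 + 1)
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-12)
        assert counts.sum() == pytest.approx(20)

    def test_too_short_sequence_names_id(self):
        with pytest.raises(ValueError, match="m7"):
            kmer_profile(SequenceRecord("m7", "AC"), k=3)

    def test_normalization_over_random_sequences(self, rng):
        # profiles lie on the simplex for any length >= k
        for _ in range(10_000):
            length = int(rng.integers(19, 26))
            seq = "".join(rng.choice(list("ACGU"), size=length))
            vec = kmer_profile(SequenceRecord("m", seq), k=3).vector
            assert abs(vec.sum() - 1.0) < 1e-12

    def test_matrix_stacks_in_order(self, toy_sequences):
        sm = kmer_matrix(toy_sequences, k=3)
        assert sm.ids == ("m1", "m2")
        assert sm.values.shape == (2, 64)


def _contribution_oracle(dag: DagEdges, disease: str, delta: float):
    """Max over all descending paths of delta^length, by path enumeration."""
    base = dag.term_of_disease[disease]
    nodes = dag.ancestors_closure(sorted(base))
    g = dag.graph.subgraph(nodes)
    out = {}
    for t in nodes:
        if t in base:
            out[t] = 1.0
            continue
        best = 0.0
        for b in base:
            for path in nx.all_simple_paths(g, b, t):
                best = max(best, delta ** (len(path) - 1))
        out[t] = best
    return out


class TestSemanticContribution:
    def test_single_node_dag(self):
        dag = DagEdges(edges=(), term_of_disease={"d": frozenset({"A"})})
        assert semantic_contribution(dag, "d", 0.5) == {"A": 1.0}

    def test_chain_decay(self, chain_dag):
        contrib = semantic_contribution(chain_dag, "dA", 0.5)
        assert contrib == {"A": 1.0, "P": 0.5}

    def test_diamond_max_rule(self, diamond_dag):
        contrib = semantic_contribution(diamond_dag, "dA", 0.5)
        assert contrib["R"] == pytest.approx(0.25)  # max(0.5*0.5, 0.5*0.5)

    def test_matches_path_enumeration_oracle_on_random_dags(self, rng):
        for trial in range(25):
            n = int(rng.integers(3, 13))
            terms = [f"t{i}" for i in range(n)]
            edges = tuple(
                (terms[i], terms[j])
                for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.3
            )  # i -> j with j > i is acyclic by construction
            dag = DagEdges(edges=edges, term_of_disease={"d": frozenset({terms[0]})})
            delta = float(rng.uniform(0.2, 0.9))
            got = semantic_contribution(dag, "d", delta)
            want = _contribution_oracle(dag, "d", delta)
            assert got.keys() == want.keys()
            for t in got:
                assert got[t] == pytest.approx(want[t], abs=1e-12)

    def test_semantic_value_sums(self, chain_dag, diamond_dag):
        assert semantic_value({"A": 1.0}) == 1.0
        assert semantic_value(semantic_contribution(chain_dag, "dA", 0.5)) == 1.5
        assert semantic_value(semantic_contribution(diamond_dag, "dA", 0.5)) == pytest.approx(2.25)


class TestDss:
    def test_self_similarity_is_one(self, diamond_dag):
        c = semantic_contribution(diamond_dag, "dA", 0.5)
        assert dss1(c, c) == 1.0

    def test_chain_versus_parent(self, chain_dag):
        ca = semantic_contribution(chain_dag, "dA", 0.5)
        cp = semantic_contribution(chain_dag, "dP", 0.5)
        # shared term P: (0.5 + 1) / (1.5 + 1)
        assert dss1(ca, cp) == pytest.approx(0.6)

    def test_disjoint_dags_zero(self):
        assert dss1({"A": 1.0}, {"B": 1.0}) == 0.0
        assert dss2({"A": 1.0}, {"B": 1.0}, 1.0, 1.0) == 0.0

    @pytest.mark.parametrize(
        "n_containing,n_diseases,expected",
        [(1, 2, np.log(2)), (2, 2, 0.0), (1, 10, np.log(10))],
    )
    def test_d2_information_weight(self, n_containing, n_diseases, expected):
        assert d2_contribution({"t": n_containing}, "t", n_diseases) == pytest.approx(expected)

    def test_d2_unseen_term_rejected(self):
        with pytest.raises(ValueError, match="no disease DAG"):
            d2_contribution({}, "t", 5)

    def test_dss2_shared_ubiquitous_term_contributes_zero(self, chain_dag):
        # P is in both DAGs of a 2-disease collection: weight -ln(2/2) = 0
        ca = semantic_contribution(chain_dag, "dA", 0.5)
        cp = semantic_contribution(chain_dag, "dP", 0.5)
        membership = {"A": 1, "P": 2}
        c2a = {t: d2_contribution(membership, t, 2) for t in ca}
        c2p = {t: d2_contribution(membership, t, 2) for t in cp}
        assert dss2(c2a, c2p, semantic_value(ca), semantic_value(cp)) == 0.0

    def test_dss2_rare_shared_term(self):
        # hypothetical 2-disease pool where the shared term sits in 1 DAG
        c2a = {"X": np.log(2.0)}
        c2b = {"X": np.log(2.0)}
        val = dss2(c2a, c2b, 1.5, 1.0, clip=False)
        assert val == pytest.approx(2 * np.log(2) / 2.5)

    def test_relabeling_invariance(self, rng):
        # isomorphic relabeled DAGs give identical DSS1/DSS2 matrices
        for _ in range(10):
            n = int(rng.integers(3, 9))
            terms = [f"t{i}" for i in range(n)]
            edges = tuple(
                (terms[i], terms[j])
                for i in range(n) for j in range(i + 1, n)
                if rng.random() < 0.4
            )
            tmap = {
                "d1": frozenset({terms[0]}),
                "d2": frozenset({terms[min(1, n - 1)]}),
            }
            dag = DagEdges(edges=edges, term_of_disease=tmap)
            perm = {t: f"z{rng.integers(0, 10 ** 9)}_{i}" for i, t in enumerate(terms)}
            dag2 = DagEdges(
                edges=tuple((perm[a], perm[b]) for a, b in edges),
                term_of_disease={d: frozenset(perm[t] for t in ts) for d, ts in tmap.items()},
            )
            for d in (dag, dag2):
                pass
            m1a, m2a, _ = semantic_similarity_matrices(dag, ["d1", "d2"], 0.5)
            m1b, m2b, _ = semantic_similarity_matrices(dag2, ["d1", "d2"], 0.5)
            np.testing.assert_allclose(m1a.values, m1b.values, atol=1e-12)
            np.testing.assert_allclose(m2a.values, m2b.values, atol=1e-12)


class TestGipKernel:
    def test_identical_rows_similarity_one(self):
        G = np.array([[1.0, 0.0], [1.0, 0.0]])
        K = gip_kernel(G, ["a", "b"], "KM").values
        assert K[0, 1] == pytest.approx(1.0)

    def test_orthogonal_unit_rows(self):
        G = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = gip_kernel(G, ["a", "b"], "KM", gamma_prime=1.0).values
        # mean squared norm 1 -> gamma 1 -> exp(-2)
        assert K[0, 1] == pytest.approx(np.exp(-2.0))

    def test_bandwidth_normalization(self):
        G = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        # every row norm^2 = 2 -> gamma = 1/2; distance^2 = 2
        K = gip_kernel(G, ["a", "b"], "KD").values
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_matches_double_loop_oracle(self, rng):
        G = (rng.random((20, 15)) < 0.3).astype(float)
        if G.sum() == 0:
            G[0, 0] = 1.0
        K = gip_kernel(G, [f"e{i}" for i in range(20)], "KM", gamma_prime=1.3).values
        gamma = 1.3 / np.mean([row @ row for row in G])
        for i, j in itertools.product(range(20), repeat=2):
            diff = G[i] - G[j]
            assert K[i, j] == pytest.approx(np.exp(-gamma * (diff @ diff)), abs=1e-12)

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            gip_kernel(np.zeros((3, 4)), ["a", "b", "c"], "KM")

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            gip_kernel(np.full((2, 2), 0.5), ["a", "b"], "KM")


class TestIntegration:
    def test_dm_width(self, toy_sequences):
        sm = kmer_matrix(toy_sequences, k=3)
        km = SimilarityMatrix("KM", ("m1", "m2"), np.eye(2))
        dm = integrate_mirna(sm, km)
        assert dm.width == 64 + 2
        # identity KM -> trailing block is unit basis rows
        np.testing.assert_array_equal(dm.values[:, 64:], np.eye(2))

    def test_corpus_scale_width_arithmetic(self):
        assert 64 + 901 == 965  # k=3 vocabulary plus one GIP column per miRNA

    def test_misaligned_ids_rejected(self, toy_sequences):
        sm = kmer_matrix(toy_sequences, k=3)
        km = SimilarityMatrix("KM", ("m2", "m1"), np.eye(2))
        with pytest.raises(ValueError, match="disagree"):
            integrate_mirna(sm, km)

    def test_dd_masked_average_and_fallback(self):
        ids = ("d1", "d2")
        d1 = SimilarityMatrix("DSS1", ids, np.array([[1.0, 0.6], [0.6, 1.0]]))
        d2 = SimilarityMatrix("DSS2", ids, np.array([[1.0, 0.8], [0.8, 1.0]]))
        kd = SimilarityMatrix("KD", ids, np.array([[1.0, 0.3], [0.3, 1.0]]))
        both = integrate_disease(d1, d2, kd, np.array([True, True]))
        assert both.values[0, 1] == pytest.approx(0.7)
        assert both.values[0, 0] == pytest.approx(1.0)
        masked_out = integrate_disease(d1, d2, kd, np.array([True, False]))
        assert masked_out.values[0, 1] == pytest.approx(0.3)  # KD fallback


class TestSimilarityMatrixInvariants:
    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix("KD", ("a", "b"), np.array([[1.0, 0.2], [0.4, 1.0]]))

    def test_unit_diagonal_enforced_for_kernel_roles(self):
        with pytest.raises(ValueError, match="diagonal"):
            SimilarityMatrix("KM", ("a", "b"), np.array([[0.9, 0.2], [0.2, 1.0]]))

    def test_semantic_matrices_symmetric_unit_diagonal(self, rng):
        # random DAG collection: DSS1 symmetric with unit diagonal, values in [0,1]
        terms = [f"t{i}" for i in range(8)]
        edges = tuple(
            (terms[i], terms[j]) for i in range(8) for j in range(i + 1, 8)
            if rng.random() < 0.35
        )
        tmap = {f"d{i}": frozenset({terms[int(rng.integers(0, 8))]}) for i in range(5)}
        dag = DagEdges(edges=edges, term_of_disease=tmap)
        m1, m2, mask = semantic_similarity_matrices(dag, sorted(tmap), 0.5)
        np.testing.assert_allclose(m1.values, m1.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m1.values), 1.0, atol=1e-12)
        assert ((m1.values >= 0) & (m1.values <= 1)).all()
        assert ((m2.values >= 0) & (m2.values <= 1)).all()
        assert mask.all()
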