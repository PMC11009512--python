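import numpy as np
import pytest

from muscle_mda.io_formats import DagEdges, EdgeList, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def chain_dag():
    """Two diseases: dA sits below term P (chain A->P), dP maps to P itself."""
    return DagEdges(
        edges=(("A", "P"),),
        term_of_disease={"dA": frozenset({"A"}), "dP": frozenset({"P"})},
    )


@pytest.fixture
def diamond_dag():
    """Diamond: A -> {B, C} -> R (edges child->parent)."""
    return DagEdges(
        edges=(("A", "B"), ("A", "C"), ("B", "R"), ("C", "R")),
        term_of_disease={"dA": frozenset({"A"})},
    )


@pytest.fixture
def toy_view_edges():
    """One miRNA, one drug, one disease: m-r and r-d."""
    return (
        EdgeList("miRNA", "drug", (("m1", "r1"),)),
        EdgeList("drug", "disease", (("r1", "d1"),)),
    )


@pytest.fixture
def toy_sequences():
    return [
        SequenceRecord("m1", "ACGUACGUACGUACGUACGUAC"),
        SequenceRecord("m2", "GGGGCCCCAAAAUUUUGGGGCC"),
    ]
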