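import numpy as np
import pytest

from smalf.core_data import AssociationDataset
from smalf.similarity import DiseaseDAG


@pytest.fixture
def chain_dag():
    """R -> C -> D: grandparent, parent, focus."""
    return DiseaseDAG.from_edges([("R", "C"), ("C", "D")])


@pytest.fixture
def diamond_dag():
    """R -> A -> D and R -> B -> D."""
    return DiseaseDAG.from_edges([("R", "A"), ("A", "D"), ("R", "B"), ("B", "D")])


@pytest.fixture
def sibling_dag():
    """A and B are both children of a shared root R."""
    return DiseaseDAG.from_edges([("R", "A"), ("R", "B")])


@pytest.fixture
def toy_dataset():
    """3 miRNAs x 2 diseases with a mix of associated and empty rows."""
    Y = np.array([[1, 0], [0, 1], [0, 0]], dtype=np.int8)
    return AssociationDataset(("m1", "m2", "m3"), ("A", "B"), Y)


def random_dag(rng: np.random.Generator, n_nodes: int) -> DiseaseDAG:
    """Random DAG on a fixed topological order (edges go forward only)."""
    names = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for j in range(1, n_nodes):
        parents = rng.choice(j, size=min(j, 1 + rng.integers(2)), replace=False)
        edges.extend((names[p], names[j]) for p in parents)
    return DiseaseDAG.from_edges(edges, terms=names)
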