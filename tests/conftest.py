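import numpy as np
import pytest

from pathprot import features, network
from pathprot.network import PathwayEdge, PathwayNetwork, PathwayNode


@pytest.fixture(scope="session")
def reference_net():
    return network.reference_network()


@pytest.fixture()
def chain_net():
    """A -> B -> C -> D, all activating; single forced path."""
    nodes = [
        PathwayNode("A", role="source"),
        PathwayNode("B"),
        PathwayNode("C"),
        PathwayNode("D", role="terminal"),
    ]
    edges = [PathwayEdge("A", "B", 1), PathwayEdge("B", "C", 1), PathwayEdge("C", "D", 1)]
    return PathwayNetwork(nodes, edges)


@pytest.fixture()
def y_split_net():
    """Source splitting 50/50 to an activation and an inhibition terminal."""
    nodes = [
        PathwayNode("S", role="source"),
        PathwayNode("ACT", role="terminal", polarity=1),
        PathwayNode("INH", role="terminal", polarity=-1),
    ]
    edges = [PathwayEdge("S", "ACT", 1), PathwayEdge("S", "INH", 1)]
    return PathwayNetwork(nodes, edges)


@pytest.fixture(scope="session")
def default_dataset():
    from pathprot.synthetic import generate_descriptor_dataset

    return generate_descriptor_dataset()


@pytest.fixture(scope="session")
def cleaned_default(default_dataset):
    dm, _ = default_dataset
    return features.clean_descriptors(dm)


def toy_descriptors(X, ids=None, labels=None):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    return features.DescriptorMatrix(
        compound_ids=ids or [f"C{i}" for i in range(n)],
        labels=labels or ["agonist"] * (n // 2) + ["antagonist"] * (n - n // 2),
        X=X,
        descriptor_names=[f"d{j}" for j in range(X.shape[1])],
    )
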