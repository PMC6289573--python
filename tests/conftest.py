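import numpy as np
import pytest

from sezconn.model import Connector, Neuron, SkeletonNode


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def chain_neuron():
    """3-node chain root -> a -> b along x, 1 um steps."""
    nodes = [
        SkeletonNode(1, None, np.array([0.0, 0.0, 0.0])),
        SkeletonNode(2, 1, np.array([1000.0, 0.0, 0.0])),
        SkeletonNode(3, 2, np.array([2000.0, 0.0, 0.0])),
    ]
    return Neuron(neuron_id="chain", skeleton=nodes)


@pytest.fixture
def straight_neuron():
    """10-node straight segment along x spanning 9 um."""
    nodes = [SkeletonNode(1, None, np.array([0.0, 0.0, 0.0]))]
    for i in range(2, 11):
        nodes.append(SkeletonNode(i, i - 1, np.array([(i - 1) * 1000.0, 0.0, 0.0])))
    return Neuron(neuron_id="straight", skeleton=nodes)


@pytest.fixture
def simple_connectors():
    """One polyadic connector A->(B,C) plus two A->B monads."""
    p = np.zeros(3)
    return [
        Connector("c1", ("A", p), (("B", p), ("C", p))),
        Connector("c2", ("A", p), (("B", p),)),
        Connector("c3", ("A", p), (("B", p),)),
    ]


def random_cloud(rng, n_points, scale=5000.0):
    """Random dotprops arrays: points and unit tangents."""
    pts = rng.uniform(-scale, scale, size=(n_points, 3))
    t = rng.normal(size=(n_points, 3))
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return pts, t
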