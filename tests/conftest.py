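import numpy as np
import pytest

from muxbrain.connectivity import LayerNetwork


def random_layer(n_nodes: int, p: float, seed: int, weight_scale: float = 1.0) -> LayerNetwork:
    """Erdos-Renyi layer with optional random positive weights."""
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n_nodes, n_nodes)) < p, k=1)
    w = np.where(upper, 1.0 + weight_scale * rng.random((n_nodes, n_nodes)), 0.0)
    z = w + w.T
    return LayerNetwork(z=z, band=(0.0, 1.0))


def complete_layer(n_nodes: int, weight: float = 1.0) -> LayerNetwork:
    z = weight * (np.ones((n_nodes, n_nodes)) - np.eye(n_nodes))
    return LayerNetwork(z=z, band=(0.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
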