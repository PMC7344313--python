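import numpy as np
import pytest

from ginfc.gin import GinConfig, GINNetwork
from ginfc.graphs import BrainGraph, one_hot_features
from ginfc.synthetic import CohortSpec, generate_cohort


def random_graph(rng, n, p=0.4):
    """Symmetric binary adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T


def make_brain_graph(rng, n=10, label=0, p=0.4):
    return BrainGraph(
        adjacency=random_graph(rng, n, p),
        node_features=one_hot_features(n),
        label=label,
        subject_id=f"toy-{label}",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_network():
    """Untrained 2-layer / 8-unit network on 6-node one-hot graphs.

    Batch-norm scale/shift are perturbed from their init so the eval-mode
    forward pass is a non-trivial differentiable map.
    """
    net = GINNetwork(
        GinConfig(n_layers=2, hidden_units=8, dropout_rate=0.0),
        in_features=6,
        n_nodes=6,
        seed=7,
    )
    prng = np.random.default_rng(99)
    for stages in net.mlps:
        for st in stages:
            bn = st["bn"]
            bn.gamma.data = prng.uniform(0.5, 1.5, bn.gamma.data.shape)
            bn.beta.data = prng.normal(0, 0.2, bn.beta.data.shape)
            bn.running_mean = prng.normal(0, 0.3, bn.running_mean.shape)
            bn.running_var = prng.uniform(0.5, 2.0, bn.running_var.shape)
    return net


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort with a strong planted effect, for end-to-end smoke tests."""
    spec = CohortSpec(
        n_subjects_per_class=30,
        n_regions=20,
        n_timepoints=120,
        planted_regions=frozenset(range(4)),
        effect_size=0.6,
        seed=5,
        fd_spike_prob=0.0,
    )
    return generate_cohort(spec)
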