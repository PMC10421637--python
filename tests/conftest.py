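import numpy as np
import pytest

from dcabench.graph_ensemble import CouplingMatrix, GraphSpec, generate_er_couplings
from dcabench.spin_sampler import SpinModel, exact_distribution


@pytest.fixture
def chain4_model():
    """Open 4-chain Ising model at T = 1 (beta J = 1 on adjacent pairs)."""
    entries = np.zeros((4, 4), dtype=np.int8)
    for i in range(3):
        entries[i, i + 1] = entries[i + 1, i] = 1
    return SpinModel(couplings=CouplingMatrix(entries), temperature=1.0)


@pytest.fixture
def chain4_exact(chain4_model):
    return exact_distribution(chain4_model)


@pytest.fixture
def small_er_graph():
    return generate_er_couplings(GraphSpec(n=12, mean_degree=4, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
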