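import numpy as np
import pytest

from fusedggm import (
    ConditionPair,
    SimulationSpec,
    simulate_study,
    standardize,
)


@pytest.fixture(scope="session")
def small_study():
    """A p=12 rewired two-condition study with ground truth."""
    spec = SimulationSpec("random", p=12, n1=40, n2=50,
                          rewire_fraction=0.2, seed=7)
    truth, pair = simulate_study(spec)
    return truth, pair, standardize(pair)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_pair():
    """Tiny deterministic pair (p=3) for data-model tests."""
    rng = np.random.default_rng(3)
    X1 = rng.normal(size=(8, 3))
    X2 = rng.normal(size=(10, 3))
    return ConditionPair(["a", "b", "c"], X1, X2)
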