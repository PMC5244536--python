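import numpy as np
import pytest

from dcseq import CountMatrix, GroupAssignment, SimulationDesign, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def groups_8_8():
    return GroupAssignment(np.array([1] * 8 + [2] * 8))


@pytest.fixture
def small_matrix(rng):
    """12 NB-ish features x 16 samples, count mode."""
    values = rng.poisson(50.0, size=(12, 16)).astype(float)
    return CountMatrix(values, [f"f{i}" for i in range(12)], [f"s{j}" for j in range(16)])


@pytest.fixture(scope="session")
def small_study():
    """A small planted-DC study shared by pipeline-level tests."""
    return simulate_study(SimulationDesign(n_x=10, n_y=60, n1=20, n2=20, seed=3))
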