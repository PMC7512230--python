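import numpy as np
import pytest

from mesfda import KernelSpec, ScenarioSpec, simulate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def scenario_a_sample():
    """One fixed magnitude-outlier sample: 400 curves, 10% contamination."""
    return simulate_scenario(ScenarioSpec(scenario="A", n=400, nu=0.10, m=50, seed=7))


@pytest.fixture(scope="session")
def reference_kernel():
    return KernelSpec(sigma=10.0, gamma=0.15)
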