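import numpy as np
import pytest

from mitotwin.simulate import SimConfig, simulate_truth_set


@pytest.fixture(scope="session")
def truth():
    """One simulated two-molecule truth set shared across the suite."""
    return simulate_truth_set(SimConfig(seed=1))


@pytest.fixture(scope="session")
def config():
    return SimConfig(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
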