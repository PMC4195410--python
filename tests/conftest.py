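import numpy as np
import pytest

from qtlbench.config import RunConfig
from qtlbench.pipeline import run_simulation


@pytest.fixture(scope="session")
def mini_result():
    """A complete scaled-down simulation shared across tests."""
    return run_simulation(RunConfig.mini(seed=11))


@pytest.fixture(scope="session")
def full_result():
    """One full-scale simulation (the default study conditions)."""
    return run_simulation(RunConfig.full(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
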