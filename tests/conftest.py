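import numpy as np
import pytest
from hypothesis import settings

from noisecascade import builtin_params

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from noisecascade.population_sim import SimulationConfig


@pytest.fixture(scope="session")
def params():
    """Nominal module parameter sets (input device, NOT gates, YES gate)."""
    return builtin_params()


@pytest.fixture(scope="session")
def small_sim():
    """Cheap simulation config for structural tests."""
    return SimulationConfig(n_cells=200, master_seed=7)


@pytest.fixture(scope="session")
def full_sim():
    """Study-scale simulation config: 10,000 cells per induction."""
    return SimulationConfig(n_cells=10_000, master_seed=1)
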