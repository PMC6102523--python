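import numpy as np
import pytest
from hypothesis import settings

from burpfam.synthetic_data import SimConfig, simulate_family

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def family():
    """One synthetic family shared across tests (fixed seed, A/T promoter
    background so planted element counts are exact)."""
    return simulate_family(SimConfig(seed=11, promoter_background="at_only"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
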