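import numpy as np
import pytest
from hypothesis import settings

from vetcoord import simulate as sim

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def uni_spec():
    """Unidirectional regime at the study dimensions (31 units x 10 years)."""
    return sim.preset_regimes("unidirectional_vhr_to_paaw", seed=42)


@pytest.fixture(scope="session")
def uni_panel(uni_spec):
    """Indicator panel + ground truth from the unidirectional regime."""
    panel, truth = sim.simulate_panel(uni_spec)
    return panel, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
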