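import numpy as np
import pytest

from tppsim import builtin, run_simulation


@pytest.fixture(scope="session")
def defaults():
    from tppsim.scenarios import load_defaults

    return load_defaults()


@pytest.fixture(scope="session")
def lowlevel_result():
    """Full-resolution 8.5 kW/m^2 stationary validation run (shared)."""
    return run_simulation(builtin("lowlevel_stationary"))


@pytest.fixture(scope="session")
def enter_low_result():
    """Low-speed entering run with 1.5 mm / 0.25 Hz gap motion (shared)."""
    return run_simulation(builtin("enter_low_speed"))


@pytest.fixture
def rng():
    return np.random.default_rng(20230104)
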