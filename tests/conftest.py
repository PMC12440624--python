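import numpy as np
import pytest

import hetflow as hf


@pytest.fixture(scope="session")
def consts():
    return hf.presets.DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def small_controls():
    """Reduced-size right-skewed control fixture shared across tests."""
    spec = hf.ControlFixtureSpec(cells_n=3000, particles_n=20_000)
    return hf.generate_control_fixtures(spec, np.random.default_rng(7))


@pytest.fixture(scope="session")
def degenerate_controls():
    """Constant controls: autofluorescence a=100, particle fluorescence f=10."""
    return hf.ControlData(np.full(50, 100.0), np.full(50, 10.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
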