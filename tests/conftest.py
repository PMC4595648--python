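import pytest

from clonarch.panel import synthetic_panel
from clonarch.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(random_seed=11)


@pytest.fixture(scope="session")
def panel_and_reference(config):
    return synthetic_panel(config.random_seed)


@pytest.fixture(scope="session")
def panel(panel_and_reference):
    return panel_and_reference[0]


@pytest.fixture(scope="session")
def reference(panel_and_reference):
    return panel_and_reference[1]
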