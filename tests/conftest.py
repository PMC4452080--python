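import pytest

from dynsurf.config import SimulationConfig, line_config, small_circle_config


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_circle() -> SimulationConfig:
    return small_circle_config(seed=1)


@pytest.fixture(scope="session")
def line_pattern() -> SimulationConfig:
    return line_config(seed=1)
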