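import pytest

from driftgrid import GridSpec, SimConfig


@pytest.fixture
def tiny_grid():
    return GridSpec(5, 5)


@pytest.fixture
def default_config():
    return SimConfig(seed=42)


@pytest.fixture
def small_config():
    """8x8 grid with a generation sized to the population (2N events)."""
    return SimConfig(grid=GridSpec(8, 8), steps_per_generation=128, seed=42)
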