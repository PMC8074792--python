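import numpy as np
import pytest

from memprobe import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def f66_table():
    """A small seeded F66 population shared across cytometry/dp_flow tests."""
    config = synthetic.SimulationConfig(seed=42, n_cells=5_000)
    return synthetic.simulate_f66_population(config)
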