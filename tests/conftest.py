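import numpy as np
import pytest

from socmd import (AtomTypeTable, PipelineConfig, SimulationConfig,
                   generate_system)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def lj_system():
    return generate_system("lj_fluid", 64, 0.5, seed=1)


@pytest.fixture
def lj_config():
    return SimulationConfig(dt=0.004, n_steps=10, cutoff=2.5,
                            pipeline=PipelineConfig(cutoff_radius=2.5))


@pytest.fixture
def type_table():
    return AtomTypeTable(epsilon=[1.0, 0.2, 0.05], sigma=[1.0, 3.0, 1.0])
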