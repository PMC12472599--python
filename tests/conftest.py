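import numpy as np
import pytest

from dbstdm.synth import SimulationConfig, generate_paired_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic bridging dataset at the study conditions."""
    return generate_paired_dataset(SimulationConfig(seed=7))
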