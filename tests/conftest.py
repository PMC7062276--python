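import numpy as np
import pytest

from mcpsize import synthetic


@pytest.fixture(scope="session")
def default_config():
    return synthetic.GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def five_technique_datasets(default_config):
    """The shipped calibration, generated once (exact moments, N = 300 each)."""
    return [
        synthetic.generate_technique_dataset(default_config, label)
        for label in default_config.labels
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
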