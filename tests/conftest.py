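import numpy as np
import pytest

from recombrisk.simulate import GeneratorConfig, make_panel


@pytest.fixture(scope="session")
def noiseless_panel():
    """Panel whose endpoints equal the model mean curves exactly (to the
    1e-4 count-encoding precision)."""
    records, truth = make_panel(GeneratorConfig(seed=0, noise_scale=0.0, err_noise=0.0))
    return records, truth


@pytest.fixture(scope="session")
def noisy_panel():
    """Default study-condition panel (3 replicates, SEM-scale noise)."""
    records, truth = make_panel(GeneratorConfig(seed=7))
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
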