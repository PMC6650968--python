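import numpy as np
import pytest

from thermoface.synthetic_fixtures import PhantomConfig, generate_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_sequence():
    """Noise-free, motion-free 5-frame phantom with ground truth."""
    config = PhantomConfig(n_frames=5, seed=7)
    return generate_sequence(config)


@pytest.fixture(scope="session")
def annotation(clean_sequence):
    return clean_sequence[2].annotation
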