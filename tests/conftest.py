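import numpy as np
import pytest

from ephystream import synthdata


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_noise():
    """6 trials x 500 samples x 3 channels of seeded white noise."""
    spec = synthdata.GeneratorSpec(
        n_trials=6, n_samples=500, n_channels=3, samplerate=1000.0, seed=11
    )
    data = synthdata.white_noise(spec)
    yield data
    data.close()
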