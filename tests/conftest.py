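import numpy as np
import pytest

from specfresh import SynthConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """4 days x 4 pieces x 2 states = 32 spectra over 40 points."""
    return generate(
        SynthConfig(
            n_days=4, samples_per_day_per_class=4, n_wavelengths=40, seed=11
        )
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Full default design: 240 spectra over 125 points."""
    return generate(SynthConfig(seed=21))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
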