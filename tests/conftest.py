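import numpy as np
import pytest

from octcca import SimConfig, bandpass, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 3 blocks x 6 targets at a comfortable SNR, band-passed."""
    cfg = SimConfig(n_subjects=3, n_blocks=3, duration=1.5, snr_db=10, seed=42)
    return generate_dataset(cfg).map(lambda e: bandpass(e, 7.0, 80.0))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
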