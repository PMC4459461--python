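import numpy as np
import pytest
from scipy.fft import rfftfreq

from eegrel import SynthSpec, extract_observation_matrix, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Eight normal and eight ictal surrogate segments at full duration."""
    spec = SynthSpec(n_segments=8, seed=7)
    manifest, segments = generate_dataset(spec, ["normal", "ictal"])
    return manifest, segments


@pytest.fixture(scope="session")
def small_om(small_dataset):
    _, segments = small_dataset
    return extract_observation_matrix(segments)


@pytest.fixture(scope="session")
def default_freqs():
    """One-sided frequency grid of the default STFT (512-point DFT at 173.61 Hz)."""
    return rfftfreq(512, d=1.0 / 173.61)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
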