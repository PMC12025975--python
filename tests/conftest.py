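import numpy as np
import pytest

from aftanet import ComponentSpec, generate_labeled_dataset, separable_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sinusoid_dataset():
    """Predictable coherent low-frequency sinusoids, 2 classes, fs 64."""
    specs = {"low3": [ComponentSpec(3.0, 30.0, "sinusoid")],
             "low5": [ComponentSpec(5.0, 30.0, "sinusoid")]}
    return generate_labeled_dataset(128, specs, fs=64.0, win_s=4.0,
                                    n_channels=4, noise_amp=1.0, seed=0)


@pytest.fixture(scope="session")
def separable_dataset():
    """The separable spike-wave vs alpha two-class set at 200 Hz."""
    return generate_labeled_dataset(32, separable_preset(), fs=200.0,
                                    win_s=4.0, n_channels=4, noise_amp=5.0,
                                    seed=7)
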