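import numpy as np
import pytest

from spectrograin.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_set():
    """Modest 4-class set with scatter and noise; shared across read-only tests."""
    cfg = SyntheticConfig(
        n_classes=4,
        samples_per_class=25,
        n_bands=48,
        class_separation=2.0,
        rng_seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_separable_set():
    """High-separation, scatter-free, near-noiseless set: every classifier
    should ace it."""
    cfg = SyntheticConfig(
        n_classes=3,
        samples_per_class=20,
        n_bands=40,
        class_separation=8.0,
        scatter_gain_sd=0.0,
        scatter_offset_sd=0.0,
        noise_sd_base=0.001,
        noise_sd_edge=0.0,
        rng_seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
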