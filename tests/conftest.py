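import numpy as np
import pytest

from morfse.synth import SynthConfig, gen_dataset


@pytest.fixture(scope="session")
def clean_cfg() -> SynthConfig:
    """Noise-free, texture-free configuration for reference-statistic oracles."""
    return SynthConfig(noise_sd=0.0, background_texture_amp=0.0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """50 patches (10 per cell), 64 px, default effect sizes."""
    return gen_dataset(SynthConfig(seed=5, n_per_cell=10))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
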