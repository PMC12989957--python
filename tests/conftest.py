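import numpy as np
import pytest

import spitzmil as sm


@pytest.fixture(scope="session")
def fast_spec() -> sm.CohortSpec:
    """Small, strongly separable cohort spec for CPU-scale tests."""
    return sm.CohortSpec(
        n_lesions=80,
        bag_size_range=(8, 32),
        encoder_dim=16,
        class_separation=3.0,
        noise_sd=1.0,
        signal_fraction_range=(0.3, 0.7),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_model_config() -> sm.ModelConfig:
    return sm.ModelConfig(encoder_dim=16, embed_dim=24, heads=4, n_classes=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
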