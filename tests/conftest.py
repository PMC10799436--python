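import numpy as np
import pytest

from adfuse import FusionClassifier, SyntheticConfig, generate_cohort
from adfuse.encoder import EncoderConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240119)


@pytest.fixture(scope="session")
def tiny_enc_cfg():
    """16^3-compatible encoder: 3 blocks -> 16 maps of 2x2x2 (d = 8)."""
    return EncoderConfig(n_blocks=3, filters=(6, 12, 24), final_filters=16)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Separable 16^3 cohort: 10 AD + 10 CN, strong lesion, low noise."""
    cfg = SyntheticConfig(n_ad=10, n_cn=10, grid=16, effect_size=0.5,
                          noise_sd=0.05, seed=11)
    return generate_cohort(cfg)


def tiny_classifier(**overrides) -> FusionClassifier:
    """Small 16^3 classifier used across training tests."""
    kwargs = dict(grid=16, filters=(6, 12, 24), final_filters=16, epochs=3,
                  batch_size=10, seed=0)
    kwargs.update(overrides)
    return FusionClassifier(**kwargs)
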