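import numpy as np
import pytest

from cytodm import StudyConfig, generate_paired_study


@pytest.fixture(scope="session")
def small_study():
    """A light paired study used across unit tests (20 patients, depth 5k)."""
    cfg = StudyConfig(n_patients=20, depth_range=(5_000, 5_000), seed=42)
    return generate_paired_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
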