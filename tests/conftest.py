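import numpy as np
import pytest

from sonosleep.simdata import GenConfig, build_benchmark
from sonosleep.sigproc import MelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_gen_config() -> GenConfig:
    """Reduced benchmark for fast end-to-end tests."""
    return GenConfig(
        n_source_nights=3,
        n_target_nights=3,
        n_test_nights=2,
        epochs_per_night=80,
        noise_bank_clips=8,
    )


@pytest.fixture(scope="session")
def small_benchmark():
    return build_benchmark(small_gen_config(), 7)


@pytest.fixture(scope="session")
def default_benchmark():
    """The standard desk-scale benchmark used for the ablation study."""
    return build_benchmark(GenConfig(), 42)
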