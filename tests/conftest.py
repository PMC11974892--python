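import numpy as np
import pytest

from kymocorr import SimConfig, simulate_cell_movie


def small_config(**overrides) -> SimConfig:
    """A compact movie configuration for fast unit tests."""
    defaults = dict(
        image_width_px=64,
        image_height_px=128,
        n_frames=30,
        rng_seed=123,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def noise_free(**overrides) -> SimConfig:
    base = dict(
        poisson_scale=0.0,
        read_noise_sd=0.0,
        bleach_rate_ref_per_s=0.0,
        bleach_rate_probe_per_s=0.0,
    )
    base.update(overrides)
    return small_config(**base)


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free, bleach-free two-channel movie at rho = 0.7 with truth."""
    return simulate_cell_movie(noise_free(rho=0.7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
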