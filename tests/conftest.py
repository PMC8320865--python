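import numpy as np
import pytest

from spectrafuse.synthetic import (Band, CubeSpec, LCDistribution, SensorSpec,
                                   SyntheticConfig)

FL1879 = LCDistribution(4.33, 57.66, 13.47, 13.62)
NORKOTAH = LCDistribution(4.33, 45.67, 12.96, 8.61)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_config(seed: int = 0, n_samples: int = 60) -> SyntheticConfig:
    """A scaled-down two-sensor config for fast structural tests."""
    a = SensorSpec(
        name="interactance", n_wavelengths=60, wavelength_range=(400.0, 1000.0),
        informative_bands=[Band(550.0, 25.0, 0.015), Band(800.0, 25.0, 0.02)],
        interferent_bands=[Band(550.0, 25.0, 0.012)],
        gain_sd=0.03, offset_sd=0.005, noise_sd=0.005)
    b = SensorSpec(
        name="hyperspectral", n_wavelengths=40, wavelength_range=(400.0, 1000.0),
        informative_bands=[Band(650.0, 30.0, 0.015), Band(800.0, 25.0, 0.02)],
        interferent_bands=[Band(650.0, 30.0, 0.012)],
        gain_sd=0.03, offset_sd=0.005, noise_sd=0.005)
    return SyntheticConfig(n_samples=n_samples, seed=seed, lc_dist=FL1879,
                           sensors=[a, b], cube=CubeSpec())


@pytest.fixture
def small_cfg():
    return small_config()
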