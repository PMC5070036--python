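import numpy as np
import pytest

from volvox_squirmer import ColonyGeometry, WaveParameters, envelope_modes


@pytest.fixture(scope="session")
def geometry():
    """Mean-colony geometry: matrix radius 200 um, flagella 20 um."""
    return ColonyGeometry(a0=200.0)


@pytest.fixture(scope="session")
def mean_wave():
    """Population-mean wave parameters (k=4.7, sigma=203, delta=1.68)."""
    return WaveParameters.volvox_mean()


@pytest.fixture(scope="session")
def env25(mean_wave, geometry):
    return envelope_modes(mean_wave, geometry, N=25)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
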