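import numpy as np
import pytest

from nemech import nps, synthetic


@pytest.fixture(scope="session")
def geometry() -> nps.ChannelGeometry:
    return nps.DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def bead_trace(geometry):
    """A simulated calibration run: 100 rigid 2-um beads at SNR 50."""
    beads = synthetic.bead_population(100, seed=11)
    dI = 100.0 * nps.relative_blockade(2.0, geometry, "sizing")
    trace, truth = synthetic.simulate_nps_trace(
        geometry, beads, noise_sd_na=dI / 50.0, seed=12
    )
    return trace, truth


@pytest.fixture(scope="session")
def nucleus_trace(geometry):
    """A simulated run of 60 meiotic nuclei at moderate noise."""
    particles = synthetic.nucleus_population(60, softness=1.0, seed=21)
    trace, truth = synthetic.simulate_nps_trace(
        geometry, particles, noise_sd_na=0.002, seed=22
    )
    return trace, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
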