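import numpy as np
import pytest
from hypothesis import settings

from isogeoloc import Raster, SyntheticScenario, synth_dataset, synth_raster

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def flat_raster():
    """1x10 equal-latitude raster: all cells carry equal area weight."""
    return Raster(values=np.zeros((1, 10)), x_min=0.0, y_max=1.0, dx=1.0, dy=1.0)


@pytest.fixture
def small_raster():
    """4x4 raster with distinct values for extraction arithmetic."""
    return Raster(
        values=np.arange(16, dtype=float).reshape(4, 4),
        x_min=-10.0,
        y_max=4.0,
        dx=1.0,
        dy=1.0,
    )


@pytest.fixture(scope="session")
def recovery_world():
    """The stated parameter-recovery world: n=500, noise 1 per mil, slope 0.35."""
    scenario = SyntheticScenario(seed=42, n_sites=100, n_per_site=5, noise_sd=1.0, slope=0.35)
    raster = synth_raster(scenario)
    dataset, truth = synth_dataset(scenario, raster)
    return scenario, raster, dataset, truth
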