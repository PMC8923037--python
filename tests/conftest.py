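import numpy as np
import pytest

import arexcest as ax


@pytest.fixture(scope="session")
def cest_schedule():
    return ax.canonical_cest_schedule()


@pytest.fixture(scope="session")
def cest_offsets(cest_schedule):
    return np.sort(np.asarray(cest_schedule.saturated_offsets))


@pytest.fixture(scope="session")
def wassr_schedule():
    return ax.canonical_wassr_schedule()


@pytest.fixture()
def clean_config():
    """Small phantom with every nuisance switched off (noiseless, flat
    fields, no drift): simulated data equal the analytic forward model."""
    return ax.PhantomConfig(
        grid_size=(16, 16),
        noise_sd=0.0,
        b0_constant_ppm=0.0,
        b1_constant=1.0,
        drift_start=1.0,
        drift_end=1.0,
    )


@pytest.fixture()
def clean_phantom(clean_config):
    return ax.build_phantom(clean_config, seed=11)
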