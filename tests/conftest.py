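import numpy as np
import pytest

import fovcrowd as fc
from fovcrowd.fitting import SamplerSettings


@pytest.fixture(scope="session")
def single_cell_design():
    """One condition cell on the default gap grid (9 finite gaps + unflanked)."""
    return fc.DesignSpec(
        subjects=("S1",),
        strokes={("S1", "AO"): (0.5,)},
        gaps=tuple(round(0.2 * i, 10) for i in range(9)),
        trials_per_cell=200,
    )


@pytest.fixture(scope="session")
def known_params():
    return fc.CrowdingParams(A=0.95, mu=0.5, sigma=0.2, m=-0.4, b=0.8).validate()


@pytest.fixture(scope="session")
def single_cell_trials(single_cell_design, known_params):
    truth = fc.GroundTruth({("S1", "AO", 0.5): known_params})
    return fc.simulate(single_cell_design, truth, seed=42)


@pytest.fixture(scope="session")
def quick_settings():
    """Reduced ensemble budget for unit tests that only need a rough posterior."""
    return SamplerSettings(walkers=16, steps=400, warmup=400, max_retained=500)


@pytest.fixture(scope="session")
def quick_fit(single_cell_trials, quick_settings):
    return fc.fit_condition(single_cell_trials, settings=quick_settings, seed=0)
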