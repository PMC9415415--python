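import numpy as np
import pytest

from croptime import estimate_soil_line, generate_dataset
from croptime.spectral import BANDS


@pytest.fixture(scope="session")
def survey_ds():
    """One seeded realisation of the 2019 training-cycle survey."""
    return generate_dataset("survey2019", seed=1)


@pytest.fixture(scope="session")
def cycle_b_ds():
    """One seeded realisation of the 2020 test cycle (independent seed)."""
    return generate_dataset("cycle2020", seed=101)


@pytest.fixture(scope="session")
def soil_line(survey_ds):
    return estimate_soil_line(survey_ds.bare_records()[list(BANDS)].to_numpy())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
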