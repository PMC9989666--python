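import numpy as np
import pytest

from neuroemergence.datatypes import RegionalTimeseries
from neuroemergence.synthetic_data import (
    SyntheticCohortSpec,
    generate_connectome,
    generate_var_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact three-group cohort reused by pipeline-level tests."""
    spec = SyntheticCohortSpec(
        n_regions=20,
        n_subjects_per_group={"control": 5, "MCS": 4, "UWS": 4},
        n_timepoints=200,
        seed=123,
    )
    return spec, generate_var_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def random_timeseries(rng):
    return RegionalTimeseries(data=rng.normal(size=(6, 240)), tr=2.0)


@pytest.fixture()
def small_connectome():
    return generate_connectome(12, 0.5, seed=99)
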