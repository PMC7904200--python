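import numpy as np
import pytest

from isotroph import (
    MixingSourceSet,
    Source,
    compute_region_baseline,
    get_tef,
)
from isotroph.synthetic_study import (
    synthetic_calibration_pairs,
    synthetic_consumer_table,
    synthetic_station_table,
)


@pytest.fixture(scope="session")
def study_stations():
    return synthetic_station_table(seed=0)


@pytest.fixture(scope="session")
def study_consumers():
    return synthetic_consumer_table(seed=0)


@pytest.fixture(scope="session")
def study_muscle(study_consumers):
    return [c for c in study_consumers if c.tissue.value == "muscle"]


@pytest.fixture(scope="session")
def study_liver(study_consumers):
    return [c for c in study_consumers if c.tissue.value == "liver"]


@pytest.fixture(scope="session")
def study_pairs():
    return synthetic_calibration_pairs(seed=0)


@pytest.fixture(scope="session")
def north_baseline(study_stations):
    return compute_region_baseline(study_stations, "north")


@pytest.fixture(scope="session")
def south_baseline(study_stations):
    return compute_region_baseline(study_stations, "central_south")


@pytest.fixture(scope="session")
def study_source_set(north_baseline, south_baseline):
    n, s = north_baseline, south_baseline
    return MixingSourceSet(
        sources=(
            Source("north", n.d13C_mean, n.d13C_sd, n.d15N_mean, n.d15N_sd),
            Source("central_south", s.d13C_mean, s.d13C_sd, s.d15N_mean, s.d15N_sd),
        ),
        tef=get_tef("madigan-muscle"),
    )
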