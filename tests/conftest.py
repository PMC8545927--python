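import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from comorbnet import cli_io
from comorbnet.synthetic_data import (
    DiseaseSpec,
    PlantedPair,
    SyntheticCohortSpec,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return cli_io.load_fixture("table1")


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return cli_io.load_fixture("table2")


@pytest.fixture(scope="session")
def table2_records(table2) -> pd.DataFrame:
    return table2.rename(columns={"protein": "node"})


@pytest.fixture(scope="session")
def table4_net():
    return cli_io.table4_network()


@pytest.fixture(scope="session")
def pathway_sets():
    return cli_io.load_fixture("table3")


@pytest.fixture(scope="session")
def small_cohort_spec() -> SyntheticCohortSpec:
    """5k-patient cohort with one strongly comorbid planted pair."""
    return SyntheticCohortSpec(
        n_patients=5000,
        diseases=[
            DiseaseSpec("401", 0.15),
            DiseaseSpec("585", 0.05),
            DiseaseSpec("285", 0.08),
            DiseaseSpec("486", 0.06),
        ],
        planted_pairs=[PlantedPair("401", "585", 0.3)],
        dm_type_mix={"T1D": 0.5, "T2D": 0.5},
        seed=11,
    )
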