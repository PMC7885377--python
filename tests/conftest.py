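import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from healthtraj import (
    FACTORS,
    binarize_cohort,
    build_context,
    concepts_of,
    make_table1_fixture,
    risk_table,
    split_by_stratum,
    write_cohort_csv,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    """The deterministic register-style fixture cohort (1885 patients)."""
    return make_table1_fixture()


@pytest.fixture(scope="session")
def table1_csv(table1, tmp_path_factory):
    path = tmp_path_factory.mktemp("cohort") / "table1.csv"
    write_cohort_csv(table1, path)
    return path


class StratumPipeline:
    """Context, lattice and risk table of one fixture stratum."""

    def __init__(self, records):
        self.records = records
        self.vectors = binarize_cohort(records)
        self.context = build_context(self.vectors, list(FACTORS))
        self.lattice = concepts_of(self.context)
        self.risks = risk_table(self.lattice, self.context)


@pytest.fixture(scope="session")
def older_female(table1):
    return StratumPipeline(split_by_stratum(table1)["older_female"])


@pytest.fixture(scope="session")
def older_male(table1):
    return StratumPipeline(split_by_stratum(table1)["older_male"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
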