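import pytest

from mitotriage import (
    SimulationConfig,
    load_known_pathogenic,
    mt_reference,
    paper_cohort,
)


@pytest.fixture(scope="session")
def manifest():
    return paper_cohort()


@pytest.fixture(scope="session")
def reference():
    return mt_reference()


@pytest.fixture(scope="session")
def known_table():
    return load_known_pathogenic()


@pytest.fixture(scope="session")
def cfg():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def families(manifest):
    return {f.family_id: f for f in manifest}
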