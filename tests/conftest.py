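import pytest

from mirrace import fixtures
from mirrace.primers import RaceChemistry


@pytest.fixture(scope="session")
def table1_mirnas():
    return fixtures.table1_mirnas()


@pytest.fixture(scope="session")
def table1_ath():
    return fixtures.table1_ath_orthologs()


@pytest.fixture(scope="session")
def table1_precursors():
    return fixtures.table1_precursor_regions()


@pytest.fixture(scope="session")
def table2():
    return fixtures.table2_primers()


@pytest.fixture(scope="session")
def offsets():
    return fixtures.gsp1_offsets()


@pytest.fixture(scope="session")
def chem():
    return RaceChemistry()
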