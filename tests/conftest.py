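import warnings

import pytest

import matriloop as ml
from matriloop.haplotypes import collapse_haplotypes, mask_hotspots, variable_sites, with_discordant
from matriloop.reference import DEFAULT_HOTSPOTS

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def fixture_data():
    return ml.load_paper_fixture()


@pytest.fixture(scope="session")
def masked_sequences(fixture_data):
    return mask_hotspots(fixture_data.sequences, DEFAULT_HOTSPOTS)


@pytest.fixture(scope="session")
def site_matrix(fixture_data, masked_sequences):
    return variable_sites(masked_sequences, reference=fixture_data.reference)


@pytest.fixture(scope="session")
def whole_loop(site_matrix):
    assignment, table = collapse_haplotypes(site_matrix)
    return with_discordant(assignment, table), table


@pytest.fixture(scope="session")
def hvr1_loop(site_matrix):
    restricted = site_matrix.restrict(ml.RunConfig().hvr1_interval)
    assignment, table = collapse_haplotypes(restricted)
    return with_discordant(assignment, table), table
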