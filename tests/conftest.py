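import pytest

from hsescan.synthetic import load_cis_element_fixture, load_hse_table_fixture


@pytest.fixture(scope="session")
def hse_table_rows():
    return load_hse_table_fixture()


@pytest.fixture(scope="session")
def cis_matrix():
    return load_cis_element_fixture()
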