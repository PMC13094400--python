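import pytest

from hladx.fixtures import (
    golden_figure3,
    golden_json_path,
    golden_xml_path,
    toy_catalog_path,
    toy_mac_table_path,
)
from hladx.mac import load_mac_table
from hladx.nomenclature import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog(toy_catalog_path())


@pytest.fixture(scope="session")
def mac_table():
    return load_mac_table(toy_mac_table_path())


@pytest.fixture
def golden():
    return golden_figure3()


@pytest.fixture(scope="session")
def golden_xml():
    return golden_xml_path().read_text()


@pytest.fixture(scope="session")
def golden_json():
    return golden_json_path().read_text()
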