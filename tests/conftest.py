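import pytest

from tccsel import synth


@pytest.fixture(scope="session")
def alignment():
    """Packaged pore-segment alignment (α1C + α1G, 24 rows)."""
    return synth.table4_fixture()


@pytest.fixture(scope="session")
def docking_panel():
    """Packaged phenylalkylamine docking panel (24 records)."""
    return synth.table2_fixture()


@pytest.fixture(scope="session")
def property_panel():
    """Packaged compound property panel (17 records)."""
    return synth.table3_fixture()


@pytest.fixture(scope="session")
def reference_blockers(property_panel):
    return [r for r in property_panel if r.role == "reference"]


@pytest.fixture(scope="session")
def candidate_compounds(property_panel):
    return [r for r in property_panel if r.role == "candidate"]
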