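import pytest
from hypothesis import settings

from ptmkit import fixtures, load_bundled_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ptmkit.annotation import ProteinCatalog, ProteinEntry


@pytest.fixture(scope="session")
def unimod_table():
    return load_bundled_table()


@pytest.fixture()
def small_catalog():
    return ProteinCatalog(
        [
            ProteinEntry(accession="P0A6F5", name="CH60_SYN",
                         sequence="MKAPEPTIDEKSTYWQRLMNHGACDEF"),
            ProteinEntry(accession="P00001", name="SYN1",
                         sequence="MSTYACDEFGHIKLMNPQRW"),
        ]
    )


@pytest.fixture()
def default_spec():
    return fixtures.FixtureSpec(seed=7, n_proteins=6, n_psms=200)


@pytest.fixture()
def fixture_dataset(default_spec):
    catalog = fixtures.generate_proteome(default_spec)
    psms, truth = fixtures.generate_synthetic_psms(default_spec, catalog)
    return default_spec, catalog, psms, truth
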