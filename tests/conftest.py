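import pytest

from regulaburden import assay, catalog, pipeline


@pytest.fixture(scope="session")
def cohorts():
    return catalog.load_cohorts(pipeline.fixture_path("lipg_cohorts.tsv"))


@pytest.fixture(scope="session")
def rare_catalog(cohorts):
    return catalog.load_catalog(pipeline.fixture_path("lipg_rare_variants.tsv"), cohorts)


@pytest.fixture(scope="session")
def common_catalog(cohorts):
    return catalog.load_catalog(pipeline.fixture_path("lipg_common_variants.tsv"), cohorts)


@pytest.fixture(scope="session")
def carriers():
    return catalog.CarrierTable.load(pipeline.fixture_path("lipg_carriers.tsv"))


@pytest.fixture(scope="session")
def functional_calls():
    return assay.load_calls(pipeline.fixture_path("lipg_functional_calls.tsv"))


@pytest.fixture
def hhdl(cohorts):
    return next(c for c in cohorts if c.name == "HHDL")


@pytest.fixture
def lhdl(cohorts):
    return next(c for c in cohorts if c.name == "LHDL")
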