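import pytest

from cdrh.formats_io import expand_homolog_counts, load_reference_tables


@pytest.fixture(scope="session")
def curated_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def homolog_records(curated_tables):
    return expand_homolog_counts(curated_tables)


@pytest.fixture(scope="session")
def sim_default(tmp_path_factory):
    """One default synthetic study, shared across tests that only read it."""
    from cdrh.synthetic import SimConfig, simulate

    out = tmp_path_factory.mktemp("sim_default")
    return simulate(SimConfig(seed=20260929 % 2**31), out)
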