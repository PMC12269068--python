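import pytest

import snomcd as sc


@pytest.fixture(scope="session")
def config():
    return sc.default_config()


@pytest.fixture(scope="session")
def full_db(config):
    """Augmented goethite-PMG-NOM-steric database."""
    return sc.default_database(config)


@pytest.fixture(scope="session")
def edlp(config):
    return sc.EDLParameters(config["c1_F_m2"], config["c2_F_m2"], 94.0, 10.0)


@pytest.fixture(scope="session")
def table1_db():
    return sc.load_database(sc.table1_path())
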