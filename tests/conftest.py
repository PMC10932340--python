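import numpy as np
import pytest

from vfipred import simulate


@pytest.fixture(scope="session")
def gene():
    """One default synthetic gene shared across the session (seeded)."""
    return simulate.make_gene(simulate.GenePreset(master_seed=7))


@pytest.fixture(scope="session")
def pathogenicity_data(gene):
    return simulate.make_labels(gene, "pathogenicity")


@pytest.fixture(scope="session")
def severity_data(gene):
    return simulate.make_labels(gene, "severity")


@pytest.fixture(scope="session")
def fixture_dir(gene, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    simulate.write_fixtures(gene, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
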