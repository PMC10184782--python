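import numpy as np
import pytest

from genomerisk import synthetic_cohort as syn


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """A default toy genome bundle shared across read-back tests."""
    params = syn.GenomeParams(n_coding_subs=200, n_coding_hets=200)
    out = tmp_path_factory.mktemp("bundle")
    return syn.simulate_genome(params, str(out), seed=7)


@pytest.fixture(scope="session")
def tree50():
    return syn.generate_tree(50, 1.0, seed=3)


@pytest.fixture(scope="session")
def cohort50(tree50):
    return syn.simulate_species_traits(tree50, syn.CohortParams(n_species=50, seed=4))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)
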