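import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import plantspectrum as ps


@pytest.fixture(scope="session")
def three_taxon_tree() -> ps.Phylogeny:
    return ps.read_newick("((A:1,B:1):1,C:2.5);")


@pytest.fixture(scope="session")
def small_study() -> ps.SyntheticStudy:
    """A modest synthetic study reused by read-only tests."""
    return ps.make_study(ps.SyntheticConfig(seed=11, n_species=20))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
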