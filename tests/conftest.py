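import numpy as np
import pytest
from hypothesis import settings

from bonesite.synthgen import CohortSpec, TraitArchitecture, simulate_genotypes, simulate_phenotypes

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """200 SNPs x 500 individuals, hard genotypes."""
    return simulate_genotypes(CohortSpec("TEST", 500, 200, seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """Panel plus phenotypes with the default four-trait architecture."""
    arch = TraitArchitecture()
    sim = simulate_phenotypes(small_panel, arch, seed=8)
    return small_panel, sim


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
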