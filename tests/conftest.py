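import numpy as np
import pytest

from gsbench import SimConfig, assign_trait_architecture, simulate_phenotypes, simulate_population
from gsbench.profiles import make_profile


@pytest.fixture(scope="session")
def small_population():
    """A desk-scale pedigree population: 20 founders + 3 x 75 offspring,
    200 markers on 5 chromosomes."""
    cfg = SimConfig(n_markers=200, offspring_per_generation=75, n_generations=3, seed=11)
    g, ped = simulate_population(cfg)
    return g, ped


@pytest.fixture(scope="session")
def oligogenic_dataset():
    """Oligogenic profile (5 large QTL, h2 = 0.5) with shared folds."""
    return make_profile("oligogenic", seed=5, n_markers=200, offspring_per_generation=75)


@pytest.fixture(scope="session")
def oligo_trait(small_population):
    g, _ = small_population
    arch = assign_trait_architecture(g, "oligogenic", target_h2=0.6, seed=21)
    y, truth = simulate_phenotypes(g, arch, seed=22)
    return g, arch, y, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
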