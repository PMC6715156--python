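import numpy as np
import pytest

import pleioscan as ps


@pytest.fixture(scope="session")
def small_map():
    return ps.simulate_map(n_chromosomes=5, markers_per_chr=20, chr_length_cM=80.0)


@pytest.fixture(scope="session")
def small_dosage(small_map):
    return ps.simulate_do_genomes(small_map, n_individuals=200, seed=20)


@pytest.fixture(scope="session")
def small_covariates(small_dosage):
    return ps.simulate_covariates(small_dosage.individuals, seed=21)


@pytest.fixture(scope="session")
def small_kinship(small_dosage, small_map):
    return ps.compute_kinship_loco(small_dosage, small_map)


@pytest.fixture(scope="session")
def medium_map():
    return ps.simulate_map(n_chromosomes=10, markers_per_chr=30, chr_length_cM=90.0)


@pytest.fixture(scope="session")
def medium_dosage(medium_map):
    return ps.simulate_do_genomes(medium_map, n_individuals=400, seed=30)


@pytest.fixture(scope="session")
def medium_kinship(medium_dosage, medium_map):
    return ps.compute_kinship_loco(medium_dosage, medium_map)


def gaussian_qtl_trait(dosage, marker_index, qtl_var, rng, effects=None):
    """Latent Gaussian trait with a QTL explaining ``qtl_var`` of variance."""
    if effects is None:
        effects = rng.normal(size=8)
        effects -= effects.mean()
    g = dosage.dosage[:, marker_index, :] @ effects
    g = (g - g.mean()) / g.std()
    n = dosage.n_individuals
    return np.sqrt(qtl_var) * g + np.sqrt(1 - qtl_var) * rng.normal(size=n), effects
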