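import numpy as np
import pytest

import factorscape as fs


@pytest.fixture(scope="session")
def small_factors():
    """Three well-separated signed factor matrices at R=20."""
    return fs.gen_factor_truth(3, 20, edge_density=0.3, magnitude=1.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_factors):
    """60-subject mixture cohort with mild noise, plus true loadings."""
    mats, loadings = fs.gen_cohort_matrices(
        small_factors, 60, dirichlet_alpha=0.5, noise_sd=0.05, seed=12
    )
    return mats, loadings


@pytest.fixture(scope="session")
def sphere100():
    return fs.gen_sphere_parcellation(100, seed=13)


@pytest.fixture(scope="session")
def atlas100(sphere100):
    return fs.gen_receptor_maps(sphere100, n_maps=19, smoothness=1, seed=14)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
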