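import pytest

import psfdilution as psf


@pytest.fixture(scope="session")
def pool():
    return psf.make_species_pool()


@pytest.fixture(scope="session")
def pairs(pool):
    return psf.make_pairing_design(pool)


@pytest.fixture(scope="session")
def config():
    return psf.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def dissims(pool, config):
    return psf.simulate_all_dissimilarities(pool, config)


@pytest.fixture(scope="session")
def truth(dissims, config):
    return psf.simulate_true_psf(dissims, config)


@pytest.fixture(scope="session")
def noiseless_config():
    return psf.SimulationConfig(
        seed=0, psf_noise_sd=0.0, pot_noise_sd=0.0, covariate_effect=0.0,
        biomass_cv=0.0, cover_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_truth(pool, noiseless_config):
    dis = psf.simulate_all_dissimilarities(pool, noiseless_config)
    return psf.simulate_true_psf(dis, noiseless_config)
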