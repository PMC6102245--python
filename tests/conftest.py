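import numpy as np
import pytest

import harvestssm as h
from harvestssm.inference import AgeAtHarvestModel


@pytest.fixture(scope="session")
def default_priors():
    return h.build_default_priors()


@pytest.fixture(scope="session")
def sim_pair():
    """One synthetic registry + truth at the default (study-shaped) design."""
    design = h.SimulationDesign(seed=3)
    data, truth = h.simulate(design)
    return data, truth, design


@pytest.fixture(scope="session")
def sim_data(sim_pair):
    return sim_pair[0]


@pytest.fixture(scope="session")
def sim_truth(sim_pair):
    return sim_pair[1]


@pytest.fixture(scope="session")
def model(sim_data, default_priors):
    return AgeAtHarvestModel(sim_data, default_priors)


@pytest.fixture(scope="session")
def desk_fit(sim_data, default_priors):
    """A single shared desk-scale posterior fit (used by several suites)."""
    return h.run_mcmc(sim_data, default_priors, h.desk_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
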