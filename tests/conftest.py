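import numpy as np
import pytest

from rovingdcm import (
    ErpFitter,
    ParameterSpace,
    build_default_network,
    generate_cohort,
    make_synthetic_leadfield,
    simulate_study,
)
from rovingdcm.simulate import grand_mean_parameters


@pytest.fixture(scope="session")
def network():
    return build_default_network()


@pytest.fixture(scope="session")
def space(network):
    return ParameterSpace(network)


@pytest.fixture(scope="session")
def leadfield(network):
    return make_synthetic_leadfield(network=network, seed=0)


@pytest.fixture(scope="session")
def grand_truth(space):
    """The synthetic generator's grand-mean parameter vector."""
    return grand_mean_parameters(space)


@pytest.fixture(scope="session")
def small_study():
    """A 4-subject crossover study (8 sessions), fixed seed."""
    cohort = generate_cohort(n_subjects=4, seed=11)
    sessions, gt, lf = simulate_study(cohort=cohort, seed=11)
    return cohort, sessions, gt, lf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
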