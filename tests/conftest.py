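import pytest

from dvmrank import (cosine_trajectory, closed_form_optimum, default_env,
                     default_dataset)
from dvmrank.fitness_optima import study_coefficients


@pytest.fixture(scope="session")
def linquad_env():
    return default_env("lin-quad")


@pytest.fixture(scope="session")
def hyperbolic_env():
    return default_env("hyperbolic")


@pytest.fixture(scope="session")
def study_lin():
    """Reported linear fitness coefficients for the lin-quad environment."""
    return study_coefficients("lin-quad")


@pytest.fixture(scope="session")
def discrete_base(linquad_env, study_lin):
    """Cosine optimum of the L=8 discrete fitness: the generator's base."""
    opt = closed_form_optimum(study_lin, linquad_env, cadence=8)
    return cosine_trajectory(opt.A, opt.B, L=8, C=linquad_env.C)


@pytest.fixture(scope="session")
def default_ds(linquad_env, discrete_base):
    """The study-default ranked dataset (202 strategies, 2031 pairs), seed 0."""
    return default_dataset(linquad_env, discrete_base, seed=0)


@pytest.fixture(scope="session")
def small_ds(linquad_env, discrete_base):
    """A reduced dataset for fast classifier unit tests."""
    return default_dataset(linquad_env, discrete_base, seed=0,
                           n_eps=11, n_pairs=200)
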