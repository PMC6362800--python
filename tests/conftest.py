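import numpy as np
import pytest

import dynocc as dy
from dynocc.model import CovariateSet, ModelParams, Protocol, ResolvedProbabilities, StudyDesign


def make_simple_covs(design: StudyDesign, seed: int = 0) -> CovariateSet:
    """Intercept + one standard-normal covariate per parameter class."""
    rng = np.random.default_rng(seed)
    N, R, _, T = design.shape_y
    g = rng.normal(0.0, 1.0, N)
    x_init = np.column_stack([np.ones(N), g])
    x_dyn = np.repeat(x_init[:, None, :], max(T - 1, 0), axis=1)
    w = rng.normal(0.0, 1.0, (N, R, T))
    w_local = np.stack([np.ones((N, R, T)), w], axis=-1)
    return CovariateSet(x_init, x_dyn, w_local)


def random_probs(design: StudyDesign, rng: np.random.Generator) -> ResolvedProbabilities:
    """Directly drawn probabilities in (0.05, 0.95), no link structure."""
    N, R, _, T = design.shape_y
    u = lambda size: rng.uniform(0.05, 0.95, size)
    return ResolvedProbabilities(
        psi_init=u(N),
        eps=u((N, max(T - 1, 0))),
        gam=u((N, max(T - 1, 0))),
        theta=u((N, R, T)),
        p=u(T),
    )


def random_small_instance(rng: np.random.Generator, k: int = 3):
    """A random tiny design, probabilities and simulated dataset, with
    occasional fully-unsurveyed station-years mixed in."""
    design = StudyDesign(
        int(rng.integers(1, 4)),
        int(rng.integers(1, 5)),
        k,
        int(rng.integers(1, 5)),
        Protocol.removal if rng.random() < 0.5 else Protocol.repeated,
    )
    probs = random_probs(design, rng)
    real = dy.simulate_realization(probs, None, design, rng_seed=int(rng.integers(2**31)))
    y = real.y.copy()
    mask = rng.random((design.n_units, design.n_stations, design.n_years)) < 0.15
    y[np.broadcast_to(mask[:, :, None, :], y.shape)] = np.nan
    return design, probs, y


@pytest.fixture
def small_design():
    return dy.small_design()


@pytest.fixture
def small_dataset(small_design):
    covs = dy.simulate_covariates(small_design, rng_seed=7)
    params = dy.default_params(small_design)
    real = dy.simulate_realization(params, covs, small_design, rng_seed=8)
    return small_design, covs, params, real


@pytest.fixture
def calibration_design():
    return StudyDesign(100, 8, 3, 5)


def simple_true_params(T: int) -> ModelParams:
    return ModelParams(
        beta=[0.5, 1.0],
        eta=[-0.5, -1.0],
        delta_coef=[0.0, 1.0],
        alpha=[0.5, 1.0],
        p_year=np.linspace(0.5, 0.9, T),
    )
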