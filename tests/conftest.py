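import dataclasses

import numpy as np
import pytest

import surveylca as slc


@pytest.fixture(scope="session")
def case_a_sample():
    """One case-A stratified survey sample (n=400, p=50, d=4, kappa=12.5)."""
    scenario = slc.SimulationScenario(case="A")
    rng = np.random.default_rng(20260918)
    population = slc.generate_population(scenario, rng)
    sample = slc.draw_stratified_sample(population, scenario, rng)
    return scenario, sample


@pytest.fixture(scope="session")
def short_weighted_draws(case_a_sample):
    """A short but real weighted run on the case-A sample, shared across
    postprocessing tests."""
    _, sample = case_a_sample
    cfg = slc.SamplerConfig(n_iter=800, burn_in=400, thin=5, seed=11)
    return slc.run_gibbs(sample.data, sample.weights, cfg)


@pytest.fixture
def tiny_data():
    """A 6x2 categorical matrix with d=(3,3), handy for exact oracles."""
    y = np.array([[1, 2], [1, 2], [2, 3], [3, 1], [3, 1], [2, 2]])
    return slc.CategoricalMatrix(y, np.array([3, 3]))


def make_config(**kwargs) -> slc.SamplerConfig:
    base = dict(K=8, n_iter=200, burn_in=100, thin=2, seed=5)
    base.update(kwargs)
    return slc.SamplerConfig(**base)


@pytest.fixture
def small_config():
    return make_config()


def replace_config(cfg, **kwargs):
    return dataclasses.replace(cfg, **kwargs)


def permute_draws(draws, seed=0):
    """Apply an independent random label permutation at every retained
    iteration — the label-switching adversary the postprocessing pipeline
    must be invariant to."""
    rng = np.random.default_rng(seed)
    pi = draws.pi_draws.copy()
    theta = draws.theta_draws.copy()
    z = draws.z_draws.copy()
    K = draws.K
    for t in range(draws.T):
        sigma = rng.permutation(K)
        inverse = np.argsort(sigma)
        pi[t] = draws.pi_draws[t][inverse]
        theta[t] = draws.theta_draws[t][:, :, inverse]
        z[t] = (sigma[draws.z_draws[t].astype(np.int64) - 1] + 1).astype(z.dtype)
    return slc.PosteriorDraws(
        pi_draws=pi,
        theta_draws=theta,
        z_draws=z,
        config=draws.config,
        kappa=draws.kappa,
        level_counts=draws.level_counts,
        retained_iterations=draws.retained_iterations,
    )
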