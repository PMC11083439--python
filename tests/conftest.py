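import dataclasses

import numpy as np
import pytest

from larvaniche.synthetic import SimulationConfig, simulate_cohort, simulate_two_cohorts


def noise_free_config(**overrides) -> SimulationConfig:
    """A generator config with every stochastic spread set to zero."""
    base = dict(
        sigma_resid=0.0,
        sigma_g=0.0,
        sigma_iso=0.0,
        cn_sd=0.0,
        maternal_d15n_sd=0.0,
        maternal_d13c_sd=0.0,
        baseline_d15n_micro=(0.56, 0.0),
        baseline_d13c_micro=(-18.1, 0.0),
        baseline_d15n_meso=(1.75, 0.0),
        baseline_d13c_meso=(-17.7, 0.0),
        temp=(24.69, 0.0),
        sal=(36.38, 0.0),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def noise_free_dataset():
    cfg = noise_free_config()
    ds, truth = simulate_cohort(cfg, seed=11)
    return cfg, ds, truth


@pytest.fixture
def small_dataset():
    """One noisy cohort, defaults, fixed seed."""
    ds, truth = simulate_cohort(SimulationConfig(), seed=3)
    return ds, truth


@pytest.fixture
def two_cohort_dataset():
    from larvaniche.synthetic import default_cohort_configs

    a, b = default_cohort_configs()
    ds, truth = simulate_two_cohorts(a, b, seed=5)
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_config(config: SimulationConfig, **overrides) -> SimulationConfig:
    return dataclasses.replace(config, **overrides)
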