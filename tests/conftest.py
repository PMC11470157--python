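"""Shared fixtures: a small calibrated scenario and fast fits of both
models, reused across PPC/report tests to keep the suite quick."""

from __future__ import annotations

import numpy as np
import pytest

import nestfidelity as nf
from nestfidelity.data_model import build_exposure_intervals
from nestfidelity.inference import MCMCConfig, fit_fidelity, fit_survival


@pytest.fixture(scope="session")
def small_scenario() -> nf.ScenarioConfig:
    """A reduced version of the calibrated scenario (~200 pairs) for
    tests that need a fitted posterior but not study-scale power."""
    cfg = nf.default_scenario(seed=7)
    cfg.n_individuals = 80
    return cfg


@pytest.fixture(scope="session")
def small_sim(small_scenario):
    return nf.simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_fidelity_fit(small_scenario, small_sim):
    prior = nf.DailySurvivalPrior.neutral(small_scenario.years)
    cfg = MCMCConfig(n_chains=3, n_iterations=3000, n_burnin=1500, seed=11)
    return fit_fidelity(small_sim.pairs, prior, cfg)


@pytest.fixture(scope="session")
def small_survival_fit(small_scenario, small_sim):
    intervals, _ = build_exposure_intervals(small_sim.visits)
    prior = nf.DailySurvivalPrior.neutral(small_scenario.years)
    cfg = MCMCConfig(n_chains=3, n_iterations=3000, n_burnin=1500, seed=12)
    return fit_survival(intervals, small_sim.pairs, prior, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
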