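"""Shared fixtures: programmatic survey fixtures and reusable fitted models."""

from __future__ import annotations

import pytest
from hypothesis import settings

import maihda as m

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_dataset() -> m.SurveyDataset:
    from maihda.datasets import synthetic_margins_survey

    return synthetic_margins_survey()


@pytest.fixture(scope="session")
def stress_dataset():
    """One sigma_u = 0.8 stress-scheme dataset shared across model tests."""
    truth = m.stress_truth(sigma_u=0.8, n=4000, seed=7)
    dataset, effects = m.simulate_survey(truth)
    return truth, dataset, effects


@pytest.fixture(scope="session")
def stress_fit_m1(stress_dataset):
    _, dataset, _ = stress_dataset
    model = m.MAIHDAModel(dataset, "hu_within", tier="model1_null")
    return model.fit(m.McmcConfig.test_scale(seed=2))


@pytest.fixture(scope="session")
def stress_fit_m2(stress_dataset):
    _, dataset, _ = stress_dataset
    model = m.MAIHDAModel(dataset, "hu_within", tier="model2_main")
    return model.fit(m.McmcConfig.test_scale(seed=1))


@pytest.fixture(scope="session")
def small_fit():
    """Tiny 8-stratum fit for structural/serialisation tests (fast)."""
    scheme = m.stress_scheme((2, 2, 2))
    prev = {f.name: (0.5, 0.5) for f in scheme.factors}
    truth = m.SimulationTruth(
        scheme=scheme,
        factor_prevalences=prev,
        intercept=-0.3,
        main_effects={("f1", "c1"): 0.4},
        sigma_u=0.4,
        n=400,
        seed=3,
    )
    dataset, _ = m.simulate_survey(truth)
    model = m.MAIHDAModel(dataset, "hu_within", tier="model2_main")
    cfg = m.McmcConfig(chains=2, iterations=600, burn_in=200, seed=9)
    return model.fit(cfg, check_convergence=False)
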