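"""Shared fixtures: small simulated subjects and cohorts.

Everything is generated programmatically from fixed seeds; session scope
keeps the more expensive simulations shared across test modules.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import taskpred as tp
from taskpred._utils import spawn_seeds

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design_table():
    """One default-design session (9 runs x 50 trials), seed 7."""
    return tp.generate_trial_sequence(tp.DesignConfig(), seed=7)


@pytest.fixture(scope="session")
def noisy_subject(design_table):
    """One simulated subject with moderate noise (sigma = 0.1)."""
    params = tp.SubjectParams.from_beta(alpha=0.4, beta=0.3, c_int=0.15, sigma=0.1)
    trials = tp.simulate_behavior(design_table, params, seed=11)
    return trials, params


@pytest.fixture(scope="session")
def small_cohort():
    """12 simulated subjects (sigma = 0.05) with their true parameters."""
    pop = tp.PopulationSpec(sigma=0.05)
    cohort = tp.sample_cohort(12, pop, seed=5)
    seeds = spawn_seeds(5, 24)
    tables = []
    for i, p in enumerate(cohort):
        t = tp.generate_trial_sequence(tp.DesignConfig(), seeds[2 * i], subject=f"sub-{i:02d}")
        tables.append(tp.simulate_behavior(t, p, seeds[2 * i + 1]))
    return tables, cohort
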