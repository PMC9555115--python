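import numpy as np
import pytest
from hypothesis import settings

from extcox.cohort import SimulationConfig, generate_cohort, make_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort():
    return make_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A simulated cohort with a healthy number of events for fit tests."""
    return generate_cohort(
        SimulationConfig(n_patients=400, seed=5, baseline_rates=(4e-4, 4e-4))
    )


def random_survival_data(seed, n=80, p=2, ties=False):
    """Small right-censored datasets for oracle comparisons."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=0.7, size=p)
    T = rng.exponential(np.exp(-(X @ beta)))
    C = rng.exponential(np.median(T) * 2.5, size=n)
    t = np.minimum(T, C)
    e = (T <= C).astype(float)
    if ties:
        t = np.ceil(t * 8) / 8  # coarse grid induces heavy ties
    return X, t, e


def structure_recovery_config(seed):
    """Study conditions for the selection-consistency simulations: n=2000,
    true effects on grade, N, Ki67>=60, PR>=20 and age>=55 only, and a
    baseline high enough to give a realistic long-follow-up event yield."""
    return SimulationConfig(
        n_patients=2000,
        seed=seed,
        coefficients={
            "grade": 1.329,
            "n_stage": 0.972,
            "ki67_high": 1.650,
            "pr_high": -1.802,
            "age_ge55": 1.378,
            "age_ge41": 0.0,
            "pr_age_post": 0.0,
        },
        baseline_rates=(4e-4, 4e-4),
    )


def threshold_recovery_config(seed, n=5000):
    """Change-point recovery conditions: default coefficients (strong
    post-threshold interaction), elevated event yield."""
    return SimulationConfig(n_patients=n, seed=seed, baseline_rates=(4e-4, 4e-4))
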