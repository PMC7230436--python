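import numpy as np
import pytest

import healecon as h


@pytest.fixture(scope="session")
def params():
    """One synthetic parameter set shared by read-only tests."""
    return h.generate_parameter_set(h.FixtureConfig(seed=3))


@pytest.fixture(scope="session")
def null_params():
    """Inert parameter set: the closed-form life-table limit."""
    return h.generate_null_parameter_set(h.FixtureConfig(seed=11))


@pytest.fixture(scope="session")
def effect_full():
    """The doubled-behaviour program: obesity odds 0.7, behaviours 2.0."""
    return h.ProgramEffect(obesity_or=0.7, activity_or=2.0, fruit_or=2.0, vegetable_or=2.0)


@pytest.fixture(scope="session")
def baseline_trace(params):
    return h.run_cohort(params)


def random_distribution(rng: np.random.Generator) -> h.JointRiskDistribution:
    return h.JointRiskDistribution(rng.dirichlet(np.ones(24)))
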