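import pytest

from serialorder.design import DesignSpec, assign_location_sets, make_experiment
from serialorder.simulate import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def design_spec():
    return DesignSpec(seed=1, participant=1)


@pytest.fixture(scope="session")
def design_table(design_spec):
    return make_experiment(design_spec)


@pytest.fixture(scope="session")
def location_sets(design_spec):
    return assign_location_sets(design_spec)


@pytest.fixture(scope="session")
def small_cohort(design_table):
    """Eight simulated participants on the standard design (race model)."""
    params = SimParams(seed=7, n_participants=8)
    return simulate_cohort(design_table, params)
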