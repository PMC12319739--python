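import numpy as np
import pytest

from episcale import (ExperimentDesign, ParticipantModel, generate_schedule,
                      simulate_responses)
from episcale.boldsim import compact_design


@pytest.fixture(scope="session")
def default_design():
    return ExperimentDesign(rng_seed=7)


@pytest.fixture(scope="session")
def default_schedules(default_design):
    return generate_schedule(default_design)


@pytest.fixture(scope="session")
def identity_responses(default_design, default_schedules):
    """A distortion-free participant: recalled == truth everywhere."""
    return simulate_responses(default_schedules, ParticipantModel(rng_seed=3),
                              default_design, participant_id="sub-identity")


@pytest.fixture(scope="session")
def small_design():
    return compact_design(n_runs=1, episodes_per_run=16, seed=11)


@pytest.fixture(scope="session")
def small_schedules(small_design):
    return generate_schedule(small_design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
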