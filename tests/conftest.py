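import numpy as np
import pytest

from nfdcm.generative_model import DCMParameters, InputSet
from nfdcm.model_space import full_modulation_spec, winning_architecture
from nfdcm.synthetic_cohort import (
    SubjectProfile,
    design_events,
    make_block_design,
    sample_cohort,
    sample_subject_params,
)


@pytest.fixture(scope="session")
def training_design():
    return make_block_design()


@pytest.fixture(scope="session")
def training_inputs(training_design):
    return InputSet.from_events(design_events(training_design))


@pytest.fixture(scope="session")
def full_spec():
    return full_modulation_spec(winning_architecture())


@pytest.fixture(scope="session")
def example_params():
    """Deterministic parameter set on the winning architecture."""
    A = np.full((4, 4), 0.0)
    np.fill_diagonal(A, -0.5)
    for t, s in [(1, 0), (0, 1), (2, 1), (1, 2), (3, 0), (0, 3), (3, 1), (1, 3), (3, 2), (2, 3)]:
        A[t, s] = 0.15
    B = np.zeros((4, 4))
    B[3, 0] = 0.4
    C = np.zeros(4)
    C[0] = 0.06
    return DCMParameters(A=A, B=B, C=C)


@pytest.fixture(scope="session")
def learner_profile():
    return SubjectProfile(
        subject_id="sub-01",
        group_label="learner",
        true_params=sample_subject_params("learner", 7),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2 + 2 subjects, 2 training runs: shared across modules."""
    return sample_cohort(n_learners=2, n_non_learners=2, seed=11, n_training_runs=2)
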