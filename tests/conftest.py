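import numpy as np
import pytest

from pescale.cohort import CohortSpec, generate_cohort
from pescale.task import build_task_design


@pytest.fixture(scope="session")
def task_design():
    return build_task_design(pairing_scheme=1, session_order=0, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Three synthetic participants at the default study conditions."""
    spec = CohortSpec(n_participants=3, seed=11)
    dataset, truth = generate_cohort(spec)
    return spec, dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
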