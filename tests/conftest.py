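import numpy as np
import pytest

from tlscreen import CohortConfig, DEFAULT_SPEC, generate_normative

TOTAL_SUBTESTS = [s.name for s in DEFAULT_SPEC.total_contributing]


@pytest.fixture(scope="session")
def normative_cohort():
    """One synthetic normative cohort at the study size, with the total."""
    cohort = generate_normative(CohortConfig(n=480, seed=1))
    return cohort.assign(total=cohort[TOTAL_SUBTESTS].sum(axis=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
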