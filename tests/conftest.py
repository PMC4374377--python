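import numpy as np
import pytest

from tbipred.synthetic_data import CohortSpec, fixture_cohort, fixture_tables, generate_cohort


@pytest.fixture(scope="session")
def tables():
    """The published univariable contingency tables."""
    return fixture_tables()


@pytest.fixture(scope="session")
def printed_cohort():
    """A 39/156 cohort whose per-variable margins equal the printed counts."""
    return fixture_cohort(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A default synthetic draw at the study's size (39 cases, 156 controls)."""
    return generate_cohort(CohortSpec(n_cases=39, seed=1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
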