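import numpy as np
import pytest

from trialpref import cohort as cohort_mod
from trialpref.trial_design import load_schema


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def truth():
    return cohort_mod.load_truth()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-respondent simulated study shared across read-only tests."""
    return cohort_mod.generate_cohort({"n": 300}, seed=11)


@pytest.fixture(scope="session")
def big_covariates():
    """A 10,000-respondent covariate table for distributional checks."""
    return cohort_mod.sample_covariates(n=10_000, rng=np.random.default_rng(42))
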