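import numpy as np
import pytest

from sepsisthresh.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def hinge_cohort_20k():
    """Large synthetic cohort at the default U-shaped risk (K=3.3,
    OR_below=0.60, OR_above=1.28) for parameter-recovery checks."""
    spec = CohortSpec(n_patients=20_000, seed=20240, missing_rates={})
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Cohort at the published study's size (n=724) with default missingness."""
    spec = CohortSpec(n_patients=724, seed=7)
    return spec, generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
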