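import numpy as np
import pytest

from scalefree import CohortSpec, gen_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-region cohort with short recordings, for plumbing tests."""
    spec = CohortSpec(regions={"A": 1.5, "B": 2.0}, n_subjects_per_region=3,
                      n_channels_per_subject=2, duration_s=10.24, seed=11)
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def cohort_ab():
    """Two regions with distinct exponents at full recording length."""
    spec = CohortSpec(regions={"A": 1.5, "B": 2.0}, n_subjects_per_region=10,
                      n_channels_per_subject=2, duration_s=60.0, seed=7)
    return gen_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
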