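import pytest

from bloodlcl.pipeline import classify_samples
from bloodlcl.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40+40 default-parameter cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_blood=40, n_lcl=40, seed=11))


@pytest.fixture(scope="session")
def small_cohort_calls(small_cohort):
    calls, panels = classify_samples(small_cohort)
    return calls, panels


@pytest.fixture(scope="session")
def noise_free_config():
    """Default cohort settings with every noise source switched off."""
    return CohortConfig(
        n_blood=0, n_lcl=0, seed=0,
        fluorescence_noise_sd=0.0, ct_jitter_sd=0.0,
        melt_noise_sd=0.0, methylation_noise_sd=0.0,
    )
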