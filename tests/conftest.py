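import pytest
from hypothesis import HealthCheck, settings

from circakit import StudyConfig, generate_cohort

settings.register_profile(
    "circakit",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("circakit")


@pytest.fixture(scope="session")
def small_config():
    """A reduced study design: 6 ADHD / 5 control subjects, 3 days of actigraphy."""
    return StudyConfig(seed=11, n_adhd=6, n_control=5, days=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
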