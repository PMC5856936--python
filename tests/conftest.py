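import hypothesis
import numpy as np
import pytest

from registrysim import (
    CancerTypeSpec,
    HospitalProfile,
    MONTH_DAYS,
    default_mixture,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20180301)


@pytest.fixture
def mixture():
    return default_mixture()


@pytest.fixture
def hospital():
    """A single high-volume (monthly-tier) facility."""
    return HospitalProfile(
        hospital_id="H01",
        annual_caseload=350,
        suspense_wait=120.0,
        submission_interval=MONTH_DAYS,
    )


@pytest.fixture
def small_hospital():
    """A quarterly-tier facility."""
    return HospitalProfile(
        hospital_id="Q01",
        annual_caseload=80,
        suspense_wait=110.0,
        submission_interval=365.0 / 4.0,
    )


@pytest.fixture
def breast_only():
    return [CancerTypeSpec("breast", 24.0, 14.0, 40.0, 1.0)]
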