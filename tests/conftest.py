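import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oxalipk import PKParams, default_pop_model, fit_foce, generate_study
from oxalipk.foce import FitOptions

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: fixed master seed for the reference synthetic study used across tests
STUDY_SEED = 1


@pytest.fixture(scope="session")
def table3_params() -> PKParams:
    """The final-model typical values used as generator truth."""
    return PKParams(v1=0.44, v2=2.26, cl=1.76, cl2=1.0)


@pytest.fixture(scope="session")
def pop_truth():
    return default_pop_model()


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (30 rats, fixed seed, no renal effect)."""
    return generate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def default_fit(default_study):
    """FOCE fit of the default study, shared by the validation tests."""
    return fit_foce(default_study, options=FitOptions(compute_se=False))
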