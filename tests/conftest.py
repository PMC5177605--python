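import warnings

import pytest
from hypothesis import HealthCheck, settings

from gliamass import default_params
from gliamass.model import NegativeConcentrationWarning

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    """Reference parameter set (NIS regime)."""
    return default_params()


@pytest.fixture
def params_ratio():
    """Factory: reference set with the feedback-gain ratio overridden
    (mG_I stays 1 mV, so ratio == mG_P)."""

    def make(ratio: float):
        return default_params().replace(mG_P=ratio)

    return make


@pytest.fixture(autouse=True)
def _quiet_concentration_warnings():
    # long stochastic runs can graze zero concentration; the warning is
    # exercised explicitly in its own test
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeConcentrationWarning)
        yield
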