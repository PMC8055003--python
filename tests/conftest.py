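import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rdna_homeostasis.feedback_model import FeedbackParams

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

WT_VOLUME = 42.0
WT_REPEATS = 125.0


@pytest.fixture(scope="session")
def wt_params() -> FeedbackParams:
    """Default parameters, calibrated to 125 repeats at the 42 fL wild type."""
    return FeedbackParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210407)
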