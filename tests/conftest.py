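import numpy as np
import pytest

from limbaug.datamodel import AnthropometricProfile
from limbaug.synthetic import generate_trial


@pytest.fixture(scope="session")
def profile():
    return AnthropometricProfile(subject_id="S000", sex_code=1,
                                 height=1.76, weight=74.0)


@pytest.fixture(scope="session")
def gait_trial(profile):
    """A 2-second noiseless-landmark gait trial (keypoints carry 5 mm
    noise), shared read-only across tests."""
    return generate_trial(profile, "gait", 2.0, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240317)
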