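import numpy as np
import pytest

from imugait.calibration import HIP_JC_KEYS, Priors
from imugait.synthesis import generate_trial


@pytest.fixture(scope="session")
def walking_trial():
    """Short noise-free walking trial shared by read-only tests."""
    return generate_trial("walking", seed=11, duration=6.0)


@pytest.fixture(scope="session")
def degenerate_trial():
    """Noise-free walking with identically-zero hip ab/ad and int/ext."""
    return generate_trial("walking", seed=12, duration=6.0, degenerate_1dof=True)


@pytest.fixture(scope="session")
def calibration_trial():
    """Short noise-free calibration-motion trial."""
    return generate_trial("calibration", seed=13, duration=12.0)


def truth_priors(trial, sigma=0.005):
    """Hip-vector priors at the generator's truth with a small covariance."""
    return Priors(
        {k: (trial.truth_calibration.jc[k], np.eye(3) * sigma**2) for k in HIP_JC_KEYS}
    )
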