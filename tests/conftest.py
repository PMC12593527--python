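import numpy as np
import pytest

from pmpscan.experiments import ExperimentConfig, exact_calibration
from pmpscan.fixtures import make_frustum


@pytest.fixture(scope="session")
def config_full():
    """Reference rig configuration at full camera resolution."""
    return ExperimentConfig()


@pytest.fixture(scope="session")
def config_small():
    """Reduced-resolution configuration for fast rendering tests."""
    return ExperimentConfig().scaled(0.35)


@pytest.fixture(scope="session")
def ideal_calib_small(config_small):
    return exact_calibration(config_small)


@pytest.fixture(scope="session")
def ideal_calib_full(config_full):
    return exact_calibration(config_full)


@pytest.fixture(scope="session")
def frustum():
    return make_frustum()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
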