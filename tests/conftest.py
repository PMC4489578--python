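import math

import numpy as np
import pytest

from v1action.gabor import BankSpec, GaborParams


@pytest.fixture(scope="session")
def default_bank() -> BankSpec:
    """The standard two-speed bank (1 and 3 ppF, 4 orientations +
    non-oriented), with channel gain calibration."""
    return BankSpec()


@pytest.fixture(scope="session")
def raw_bank() -> BankSpec:
    """Uncalibrated bank for micro-tests that look at one channel."""
    return BankSpec(calibrate=False)


@pytest.fixture()
def slow_params() -> GaborParams:
    return GaborParams(v=1.0, theta=0.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
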