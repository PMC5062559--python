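import numpy as np
import pytest

from tensionmap import calibration as cal


@pytest.fixture(scope="session")
def model() -> cal.CalibrationModel:
    """Calibration model fitted from the packaged synthetic default tables."""
    return cal.default_calibration_model()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
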