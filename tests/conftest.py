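import numpy as np
import pytest

from goggleskit.eyetrack import CalibrationParams
from goggleskit.fieldmap import DisplayMapping


@pytest.fixture(scope="session")
def mapping() -> DisplayMapping:
    """Default eyepiece mapping: 1.57 px/deg over a 140-degree FOV."""
    return DisplayMapping()


@pytest.fixture(scope="session")
def calib() -> CalibrationParams:
    """A plausible hand-set eye-camera calibration used across tests."""
    return CalibrationParams(a=0.02, b=0.9, c=0.4, d=20.0, k=420.0)


@pytest.fixture(scope="session")
def mm_grid() -> np.ndarray:
    """A 7x7 millimeter-spaced calibration grid spanning +/-1.5 mm."""
    gx, gy = np.meshgrid(np.arange(-1.5, 1.6, 0.5), np.arange(-1.5, 1.6, 0.5))
    return np.column_stack([gx.ravel(), gy.ravel()])
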