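import numpy as np
import pytest

from redoxratio.redox_core import PhysicalConstants, ProbeCalibration


@pytest.fixture
def calib() -> ProbeCalibration:
    """Spec-style calibration: r_ox=2.0, r_red=0.5, endpoint quotient 0.6."""
    return ProbeCalibration(r_ox=2.0, r_red=0.5, i490_min=0.6, i490_max=1.0)


@pytest.fixture
def const() -> PhysicalConstants:
    return PhysicalConstants()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def mixture_forward_ratio(oxd, calib: ProbeCalibration):
    """Independent endpoint-mixture forward model for the probe's ratio.

    Each channel is a linear mixture of the fully oxidised and fully
    reduced species' intensities; the long channel endpoints are
    i490_min (oxidised) and i490_max (reduced), the short channel
    endpoints follow from the endpoint ratios.  R = I_short / I_long.
    """
    oxd = np.asarray(oxd, dtype=float)
    short_ox = calib.r_ox * calib.i490_min
    short_red = calib.r_red * calib.i490_max
    i_long = calib.i490_max + oxd * (calib.i490_min - calib.i490_max)
    i_short = short_red + oxd * (short_ox - short_red)
    return i_short / i_long
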