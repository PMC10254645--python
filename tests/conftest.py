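import numpy as np
import pytest

from spicpms import (
    AcquisitionMeta,
    FlowRate,
    IonicCalibration,
    TransportEfficiency,
)

Q_SAM = 0.35e-3 / 60.0  # 0.35 mL/min in L/s


@pytest.fixture
def flow():
    return FlowRate(q_sam=Q_SAM)


@pytest.fixture
def cal():
    return IonicCalibration(slope_s=1e6, intercept=0.0, r_squared=1.0)


@pytest.fixture
def eta075():
    return TransportEfficiency(eta_neb=0.075)


@pytest.fixture
def short_meta():
    """A 12 s acquisition (1.2e5 dwells) for fast simulations."""
    return AcquisitionMeta(total_time=12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
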