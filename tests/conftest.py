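import numpy as np
import pytest

from enzkin.gfet_signal import CalibrationModel
from enzkin.kinetics import KineticParameters, MMState, simulate_mm


@pytest.fixture(scope="session")
def qss_params():
    """MM parameters deep in the quasi-steady-state regime."""
    return KineticParameters(k1=10.0, k2=500.0, k_cat=5.0, E_total=0.01)


@pytest.fixture(scope="session")
def qss_trajectory(qss_params):
    init = MMState(S=100.0, E=qss_params.E_total, C=0.0, P=0.0)
    times = np.linspace(0.0, 60.0, 121)
    return simulate_mm(qss_params, init, times)


@pytest.fixture(scope="session")
def unit_calibration():
    """Origin-anchored calibration: 2 μA/μM, linear from 10 to 70 μM."""
    return CalibrationModel(
        slope=2.0, intercept=0.0, linear_range=(10.0, 70.0), r2=1.0, residual_sd=0.0
    )
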