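import numpy as np
import pytest

from clsecretion import PathwayState, TissueParams, UssingMeasurement
from clsecretion.constants import DEFAULT_G_A0, DEFAULT_V0


@pytest.fixture(scope="session")
def tissue() -> TissueParams:
    return TissueParams()


@pytest.fixture(scope="session")
def baseline_state() -> PathwayState:
    """Stylized baseline: G_B0 = 30*G_A0 at -40 mV."""
    return PathwayState(
        g_apical=DEFAULT_G_A0, g_basolateral=30 * DEFAULT_G_A0, v_membrane=DEFAULT_V0
    )


@pytest.fixture(scope="session")
def table2() -> UssingMeasurement:
    """Measured baseline/stimulated currents and blocker-sensitive
    conductances of the forskolin experiment."""
    return UssingMeasurement(
        i_a0=0.08, i_a_inf=6.40, g_a0=12.87, g_b0=360.00, g_a_inf=689.04, g_b_inf=480.47
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20151223)
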