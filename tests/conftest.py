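import numpy as np
import pytest

from irmkin import HeatingRamp, KineticProcess, simulate_conversion


@pytest.fixture(scope="session")
def study_ramp():
    """1 °C·min⁻¹ ramp over the hot-stage window used throughout."""
    return HeatingRamp.from_celsius(25.0, 150.0, 1.0)


@pytest.fixture(scope="session")
def jma3_process():
    """Slow-crystallizing JMA process (E = 50 kJ·mol⁻¹, lnA = 10, m = 3)."""
    return KineticProcess("jma", E=50e3, lnA=10.0, m=3.0)


@pytest.fixture(scope="session")
def jma3_trace(jma3_process, study_ramp):
    return simulate_conversion(jma3_process, study_ramp)


@pytest.fixture(scope="session")
def fast_process():
    """High-barrier first-order process (E = 200 kJ·mol⁻¹, lnA = 70)."""
    return KineticProcess("jma", E=200e3, lnA=70.0, m=1.0)
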