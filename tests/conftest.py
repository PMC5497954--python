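import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pegcascade as pc
from pegcascade.calibration import calibrated_parameters

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> pc.ModelParameters:
    return pc.ModelParameters()


@pytest.fixture(scope="session")
def calibrated_params() -> pc.ModelParameters:
    """Model calibrated once per session against the printed PK anchors."""
    return calibrated_parameters(seed=0)


@pytest.fixture(scope="session")
def nktr_simulation(calibrated_params) -> pc.SimulationResult:
    """Single 0.8 mg/kg prodrug dose on a quarter-hour grid out to 340 h."""
    t = np.arange(0.0, 340.0 + 0.25, 0.25)
    return pc.simulate(calibrated_params, pc.DoseRegimen.single_bolus(), t)


@pytest.fixture(scope="session")
def aldesleukin_simulation(calibrated_params) -> pc.SimulationResult:
    t = np.arange(0.0, 240.0 + 0.25, 0.25)
    regimen = pc.DoseRegimen.single_bolus(0.8, "aldesleukin")
    return pc.simulate(calibrated_params, regimen, t)
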