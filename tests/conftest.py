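import numpy as np
import pytest

from mockloop import (
    LoopConfig,
    PumpModel,
    ThermalModel,
    ThermostatController,
    TurbineSensor,
    VenousWaveformParams,
)
from mockloop.hydraulics import pump_inflow_profile
from mockloop.waveforms import discretize_to_steps, venous_waveform


@pytest.fixture
def params():
    return VenousWaveformParams()


@pytest.fixture
def svc_wave(params):
    return venous_waveform(params, "SVC", 256)


@pytest.fixture
def ivc_wave(params):
    return venous_waveform(params, "IVC", 256)


@pytest.fixture
def inflow(svc_wave, ivc_wave):
    return pump_inflow_profile(svc_wave, ivc_wave, d_svc=1.27, d_ivc=2.0, d_in=2.0)


@pytest.fixture
def default_schedule(inflow):
    return discretize_to_steps(inflow, 20)


@pytest.fixture
def pump():
    return PumpModel()


@pytest.fixture
def calibrated_pump():
    return PumpModel(correction_slope=1.0, correction_intercept=0.0)


@pytest.fixture
def sensor():
    return TurbineSensor()


@pytest.fixture
def noiseless_sensor():
    return TurbineSensor(count_jitter_sd=0.0)


@pytest.fixture
def thermal_model():
    return ThermalModel()


@pytest.fixture
def thermostat():
    return ThermostatController()


@pytest.fixture
def config():
    return LoopConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
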