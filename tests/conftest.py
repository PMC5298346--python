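import numpy as np
import pytest

from hvkit.biophysics import SolutionConditions
from hvkit.simulate import (GatingParams, NoiseModel, VoltageProtocol,
                            simulate_family)


@pytest.fixture
def gating():
    return GatingParams()


@pytest.fixture
def quiet_noise():
    return NoiseModel()


@pytest.fixture
def symmetric_conditions():
    return SolutionConditions(pH_o=7.0, pH_i=7.0, temperature_C=21.0)


@pytest.fixture
def default_protocol():
    # spans the symmetric-pH activation range; dt satisfies the
    # undersampling guard down to the 1 ms tau floor
    return VoltageProtocol(holding_mV=-60.0, step_start_mV=-40.0,
                           step_stop_mV=140.0, step_increment_mV=10.0,
                           step_duration_ms=400.0, tail_duration_ms=150.0,
                           sample_interval_ms=0.2)


@pytest.fixture
def noiseless_family(default_protocol, symmetric_conditions, gating,
                     quiet_noise):
    return simulate_family(default_protocol, symmetric_conditions, gating,
                           quiet_noise)


def sweep_at(family, step_mV):
    for sw in family.sweeps:
        if abs(sw.step_mV - step_mV) < 1e-9:
            return sw
    raise AssertionError(f"no sweep at {step_mV} mV")
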