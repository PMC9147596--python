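import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from rettephys.core_io import PipelineConfig, SweepFamily, Trace
from rettephys.synthetic_data import WT_PARAMS, RTT_PARAMS


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def wt_params():
    return WT_PARAMS


@pytest.fixture
def rtt_params():
    return RTT_PARAMS


@pytest.fixture
def small_family():
    """Two-sweep current family with a capacitance, for I/O round trips."""
    rng = np.random.default_rng(7)
    dt = 0.1
    sweeps = {
        -40.0: Trace(rng.normal(-50.0, 5.0, 400), dt, units="pA", label="-40"),
        -30.0: Trace(rng.normal(-30.0, 5.0, 400), dt, units="pA", label="-30"),
    }
    return SweepFamily(sweeps, "IV_ACTIVATION", capacitance=150.0,
                       meta={"step_start_ms": 10.0, "step_dur_ms": 30.0})
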