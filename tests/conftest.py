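import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from tiltsim.core import TiltProtocol
from tiltsim.params import SubjectConfig
from tiltsim.protocol_analysis import run_protocol, steady_state_metrics


@pytest.fixture(scope="session")
def protocol_run():
    """One full tilt protocol (80 HUT -> 6 HDT -> 80 HUT) on the calibrated
    subject; shared by every steady-state comparison."""
    cfg = SubjectConfig()
    protocol = TiltProtocol()
    res = run_protocol(cfg, protocol, settle=240.0)
    return res


@pytest.fixture(scope="session")
def steady_windows(protocol_run):
    prot = protocol_run.protocol
    out = {}
    for key, i in [("pre", 0), ("hdt", 1), ("return", 2)]:
        t0, t1 = prot.window(i)
        out[key] = steady_state_metrics(protocol_run, (t1 - 60.0, t1))
    return out
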