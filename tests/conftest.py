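"""Shared fixtures: expensive simulations are session-scoped and reused."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from erspine import engine, parameters, protocols

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return parameters.default_parameters()


@pytest.fixture(scope="session")
def epsp_er_minus(params):
    """Unitary EPSP in the ER-lacking spine at the tabulated g_N."""
    return engine.run(protocols.unitary_epsp(), params, er=False)


@pytest.fixture(scope="session")
def epsp_er_plus(params):
    """Unitary EPSP in the ER-bearing spine, default N_R = 30."""
    return engine.run(protocols.unitary_epsp(), params, er=True)


@pytest.fixture(scope="session")
def quiet_100s(params):
    """Unstimulated 100 s integration from rest (ER-bearing spine)."""
    proto = protocols.StimulusProtocol(
        glu_times=(), bap_times=(), co_input=False, vgcc=False,
        duration=100.0, label="quiet")
    return engine.run(proto, params, er=True)


@pytest.fixture(scope="session")
def g_n_calibrated(params):
    """NMDAR conductance calibrated to a 0.2 uM unitary Ca2+ peak (pS)."""
    return parameters.calibrate_gN(params, 0.2)
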