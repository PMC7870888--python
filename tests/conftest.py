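"""Shared fixtures.

The expensive simulation products (calibrated models, full activation
protocols at several series resistances) are computed once per session and
shared between the unit and acceptance tests.
"""

import numpy as np
import pytest

import clampsim as cs


@pytest.fixture(scope="session")
def ina_protocol():
    return cs.VoltageStepProtocol()  # HP -100, -80..+50 by 5, 50 ms


@pytest.fixture(scope="session")
def ito_protocol():
    return cs.VoltageStepProtocol(duration_ms=100.0)


@pytest.fixture(scope="session")
def gcal_ina_10na(ina_protocol):
    """G_max giving a 10-nA peak range at R_S = 0 for the Na+ model."""
    return cs.calibrate_gmax("ina_ohara", 10.0, ina_protocol)


@pytest.fixture(scope="session")
def ina_model_10na(gcal_ina_10na):
    return cs.build_model("ina_ohara", gcal_ina_10na)


@pytest.fixture(scope="session")
def ina_fits_10na(ina_model_10na, ina_protocol):
    """Boltzmann activation fits of the 10-nA Na+ model at R_S = 0/2/5 MOhm."""
    return {
        rs: cs.activation_fit(ina_model_10na, cs.ClampConfig(rs_mohm=rs),
                              ina_protocol)
        for rs in (0.0, 2.0, 5.0)
    }


@pytest.fixture(scope="session")
def gcal_ito_100na(ito_protocol):
    return cs.calibrate_gmax("ito_ohara", 100.0, ito_protocol)


@pytest.fixture(scope="session")
def ito_fits_100na(gcal_ito_100na, ito_protocol):
    model = cs.build_model("ito_ohara", gcal_ito_100na)
    return {
        rs: cs.activation_fit(model, cs.ClampConfig(rs_mohm=rs), ito_protocol)
        for rs in (0.0, 5.0, 15.0)
    }


@pytest.fixture(scope="session")
def short_traces():
    """A small, cheap trace family for I/O and CLI tests."""
    model = cs.build_model("ina_ohara", 0.5)
    protocol = cs.VoltageStepProtocol(steps_mV=(-50.0, -35.0, -20.0, -5.0),
                                      duration_ms=5.0)
    return cs.run_protocol(model, cs.ClampConfig(rs_mohm=2.0), protocol)
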