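"""Shared fixtures: expensive simulations are session-scoped and reused."""

import numpy as np
import pytest

import smadtif as st


@pytest.fixture(scope="session")
def sustained10():
    return st.StimulusProtocol.sustained(10.0)


@pytest.fixture(scope="session")
def integrated_system():
    return st.build_model("INTEGRATED")


@pytest.fixture(scope="session")
def base_system():
    return st.build_model("BASE")


@pytest.fixture(scope="session")
def integrated_traj(integrated_system, sustained10):
    """24 h sustained-stimulation trajectory of the integrated model."""
    return st.simulate(integrated_system, sustained10)


@pytest.fixture(scope="session")
def relative_curve():
    """Model-predicted relative pS24n signal on the default ratio grid."""
    return st.predict_relative_signal([0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0])
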