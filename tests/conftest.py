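import pytest

import ventloop as vl


@pytest.fixture(scope="session")
def default_params():
    return vl.SubjectParams()


@pytest.fixture(scope="session")
def default_cfg():
    return vl.ControllerConfig()


@pytest.fixture(scope="session")
def default_vent(default_params):
    return vl.default_ventilator(default_params)


@pytest.fixture(scope="session")
def staircase_log():
    """One deterministic full default-protocol run shared across tests."""
    return vl.run_protocol(vl.default_protocol(), seed=1)


@pytest.fixture(scope="session")
def staircase_frame(staircase_log):
    return staircase_log.to_frame()
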