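import pytest

from ire1link.panel import calibrated_defaults


@pytest.fixture(scope="session")
def cal():
    """Calibrated default parameter set (computed once per session)."""
    return calibrated_defaults()


@pytest.fixture(scope="session")
def wt(cal):
    return cal.wild_type


@pytest.fixture(scope="session")
def kin(cal):
    return cal.kinetics


@pytest.fixture(scope="session")
def opt(cal):
    return cal.optics
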