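import pytest
from hypothesis import settings as hyp_settings

from cryoperf import KroghGeometry, MembraneParams, SimSettings, ToxicityParams

hyp_settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom():
    return KroghGeometry()


@pytest.fixture(scope="session")
def mem():
    return MembraneParams()


@pytest.fixture(scope="session")
def tox():
    return ToxicityParams()


@pytest.fixture(scope="session")
def settings():
    return SimSettings()
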