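import pytest
from hypothesis import HealthCheck, settings

from tagkit import construct_design as cd
from tagkit import fixtures as fx

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return fx.FixtureConfig(seed=7)


@pytest.fixture(scope="session")
def locus(cfg):
    return fx.make_locus(cfg)


@pytest.fixture(scope="session")
def vector(cfg):
    return fx.make_vector(cfg)


@pytest.fixture(scope="session")
def design(locus, vector):
    return cd.design_construct(locus, vector)
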