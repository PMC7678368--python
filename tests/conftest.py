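import pytest

from cavte.synthetic_data import base_config, generate_fixture, generate_stress_variants


@pytest.fixture(scope="session")
def fixture_ps():
    ps, _manifest = generate_fixture(0)
    return ps


@pytest.fixture(scope="session")
def manifest():
    _ps, man = generate_fixture(0)
    return man


@pytest.fixture()
def ps(fixture_ps):
    """A mutable copy of the session fixture parameter set."""
    return fixture_ps.model_copy(deep=True)


@pytest.fixture(scope="session")
def cfg():
    return base_config()


@pytest.fixture(scope="session")
def stress_variants(fixture_ps):
    return generate_stress_variants(fixture_ps, seed=0)
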