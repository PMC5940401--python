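import pytest

from bayesbasket.synthetic import default_program_spec, generate_roster


@pytest.fixture(scope="session")
def program_spec():
    return default_program_spec()


@pytest.fixture(scope="session")
def exact_roster(program_spec):
    """Exact-mode synthetic roster + site registry (shared; do not mutate)."""
    return generate_roster(program_spec, mode="exact", seed=0)
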