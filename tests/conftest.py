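import pytest
from hypothesis import settings

from aptalogic import (Conditions, DEFAULT_SEED, evaluate_truth_table,
                       generate_fixtures)
from aptalogic.halfadder import evaluate_half_adder

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cond():
    return Conditions()


@pytest.fixture(scope="session")
def fixture_set():
    """The shipped fixture set (generated once per session)."""
    return generate_fixtures(DEFAULT_SEED)


@pytest.fixture(scope="session")
def fixture_truth(fixture_set):
    """Truth tables of the four simple gates, evaluated end-to-end."""
    return {name: evaluate_truth_table(gate)
            for name, gate in fixture_set.gates.items()}


@pytest.fixture(scope="session")
def half_adder_result(fixture_set):
    return evaluate_half_adder(fixture_set.half_adder)
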