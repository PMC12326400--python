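import pytest

from pdcea.datasets import load_advanced_pd
from pdcea.states import HealthState, StateSpace


@pytest.fixture(scope="session")
def bundle():
    return load_advanced_pd()


@pytest.fixture
def two_state_space():
    """Minimal absorbing chain: one alive state with utility 1, dead."""
    return StateSpace(
        (
            HealthState(id="alive", flag="on_treatment", utility=1.0),
            HealthState(id="dead", flag="dead"),
        )
    )


@pytest.fixture
def three_state_space():
    return StateSpace(
        (
            HealthState(id="mild", flag="on_treatment", utility=0.8),
            HealthState(id="severe", flag="on_treatment", utility=0.4),
            HealthState(id="dead", flag="dead"),
        )
    )
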