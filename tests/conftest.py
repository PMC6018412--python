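import pytest

from mvlogic import LogicalModel, State, p53_mdm2_model


@pytest.fixture(scope="session")
def p53() -> LogicalModel:
    return p53_mdm2_model()


def code(s: str) -> State:
    return State.from_code(s)


def codes(states) -> list[str]:
    return sorted(s.code() for s in states)
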