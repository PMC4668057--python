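import pytest

from seamdel import (
    DEFAULT_CONSTRAINTS,
    FixtureSpec,
    MarkerSpec,
    generate_locus,
    generate_marker,
)
from seamdel.design import PrimerSet, design_target

HAPPY_SPEC = FixtureSpec(seed=2, flank_len=1000, orf_len=900, gc=0.40)


@pytest.fixture(scope="session")
def constraints():
    return DEFAULT_CONSTRAINTS


@pytest.fixture(scope="session")
def marker():
    return generate_marker(MarkerSpec(seed=1))


@pytest.fixture(scope="session")
def happy_locus():
    return generate_locus(HAPPY_SPEC)


@pytest.fixture(scope="session")
def designed(happy_locus, marker, constraints):
    outcome = design_target(happy_locus, marker, constraints)
    assert isinstance(outcome, PrimerSet), outcome
    return outcome
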