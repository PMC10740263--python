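import pytest

from igannot import build_alignment, build_model
from igannot.fixtures import make_germline_set, make_repertoire


@pytest.fixture(scope="session")
def germlines():
    """Deterministic 4 V x 3 J germline family (seed 1)."""
    return make_germline_set(1, 4, 3)


@pytest.fixture(scope="session")
def toy_alignment(germlines):
    v, j = germlines
    return build_alignment(v, j)


@pytest.fixture(scope="session")
def toy_model(toy_alignment):
    """Unreduced (alphabet 20) model trained on the fixture germlines."""
    return build_model(toy_alignment, "toy", alphabet_size=20)


@pytest.fixture(scope="session")
def zero_mut_reads(germlines):
    """50 zero-mutation reads with short CDR3 inserts, plus truth."""
    return make_repertoire(germlines, 50, (0, 10), 0.0, seed=11)
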