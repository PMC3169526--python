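import pytest

from tlskit.classification import make_aligner
from tlskit.constructs import CloneRead, default_constructs


@pytest.fixture(scope="session")
def constructs():
    """Default constructs keyed by id."""
    return {c.id: c for c in default_constructs()}

@pytest.fixture(scope="session")
def tt_cpd(constructs):
    return constructs["TT_CPD"]


@pytest.fixture(scope="session")
def aligner():
    return make_aligner()


@pytest.fixture(scope="session")
def read_with_window(constructs):
    """Factory: a clone read whose classification window is replaced.

    ``window`` is a 4-character string; "-" at a position deletes that
    nucleotide from the read.
    """

    def build(construct_id: str, window: str, clone_id: str = "clone") -> CloneRead:
        c = constructs[construct_id]
        ws = c.window_start
        body = window.replace("-", "")
        seq = c.reference[:ws] + body + c.reference[ws + 4 :]
        return CloneRead(clone_id, "cond", "rep1", seq)

    return build
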