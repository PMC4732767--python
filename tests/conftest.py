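import pytest

from mixtime.chains import BipartiteGraph, DegreeSequencePair, get_chain
from mixtime.stategraph import build_state_graph


@pytest.fixture(scope="session")
def k22():
    return BipartiteGraph(2, 2, frozenset({(0, 0), (0, 1), (1, 0), (1, 1)}))


@pytest.fixture(scope="session")
def path_graph():
    """u1 - v1 - u2: balanced but without a perfect matching."""
    return BipartiteGraph(2, 2, frozenset({(0, 0), (1, 0)}))


@pytest.fixture(scope="session")
def single_edge():
    return BipartiteGraph(1, 1, frozenset({(0, 0)}))


def build(chain_name, instance, max_states=20000):
    return build_state_graph(get_chain(chain_name), instance, max_states=max_states)


@pytest.fixture(scope="session")
def broder_k22(k22):
    return build("broder", k22)


@pytest.fixture(scope="session")
def jsv_k22(k22):
    return build("jsv", k22)


@pytest.fixture(scope="session")
def switch1_pair11():
    return build("switch1", DegreeSequencePair((1, 1), (1, 1)))


@pytest.fixture(scope="session")
def small_switch_pairs():
    """All unordered realizable degree-sequence pairs up to 3+3."""
    from mixtime.instances import enumerate_sequence_pairs

    return enumerate_sequence_pairs(3, 3, ordered=False)
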