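"""Transition-rule tests: proposal sets, kappa values, weights, validity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import all_matchings, margin_matrices
from mixtime.chains import (
    CHAINS,
    BipartiteGraph,
    DegreeSequencePair,
    MatchingState,
    RealizationState,
    arbitrary_matching,
    arbitrary_realization,
    broder_neighbours,
    get_chain,
    jsv_neighbours,
    jsv_weights,
    switch1_neighbours,
    switch2_neighbours,
)
from mixtime.errors import (
    InvalidStateError,
    NotRealizableError,
    UnsupportedInstanceError,
)
from mixtime.instances import enumerate_bipartite_graphs, enumerate_sequence_pairs


def proposal_map(proposals, origin):
    """{successor key: kappa}; the origin's own key marks the self-proposal."""
    out = {}
    for state, kappa in proposals:
        out[state.key()] = out.get(state.key(), 0.0) + kappa
    assert math.isclose(sum(out.values()), 1.0, abs_tol=1e-12)
    return out


# ---------------------------------------------------------------------------
# matching chain one (uniform edge pick)
# ---------------------------------------------------------------------------


def test_broder_perfect_state_proposals(k22):
    perfect = MatchingState(k22, frozenset({(0, 0), (1, 1)}))
    got = proposal_map(broder_neighbours(perfect), perfect)
    assert got[((0, 0),)] == pytest.approx(0.25)
    assert got[((1, 1),)] == pytest.approx(0.25)
    assert got[perfect.key()] == pytest.approx(0.5)
    assert len(got) == 3


def test_broder_near_perfect_state_proposals(k22):
    near = MatchingState(k22, frozenset({(1, 1)}))  # holes u1, v1
    got = proposal_map(broder_neighbours(near), near)
    assert got[((0, 0), (1, 1))] == pytest.approx(0.25)  # add
    assert got[((0, 1),)] == pytest.approx(0.25)  # slide
    assert got[((1, 0),)] == pytest.approx(0.25)  # slide
    assert got[near.key()] == pytest.approx(0.25)


def test_broder_single_edge_no_self_proposal(single_edge):
    empty = MatchingState(single_edge, frozenset())
    proposals = broder_neighbours(empty)
    assert len(proposals) == 1
    state, kappa = proposals[0]
    assert state.key() == ((0, 0),) and kappa == pytest.approx(1.0)


def test_broder_rejects_adjacent_edges(k22):
    bad = MatchingState(k22, frozenset({(0, 0), (0, 1)}))
    with pytest.raises(InvalidStateError):
        broder_neighbours(bad)


# ---------------------------------------------------------------------------
# matching chain two (vertex pick, weighted)
# ---------------------------------------------------------------------------


def test_jsv_perfect_state_removals_only(k22):
    perfect = MatchingState(k22, frozenset({(0, 0), (1, 1)}))
    got = proposal_map(jsv_neighbours(perfect), perfect)
    assert got == {
        ((0, 0),): pytest.approx(0.5),
        ((1, 1),): pytest.approx(0.5),
    }


def test_jsv_near_perfect_aggregates_add_move(k22):
    near = MatchingState(k22, frozenset({(1, 1)}))
    got = proposal_map(jsv_neighbours(near), near)
    # both hole vertices trigger the add move: kappa = 2 * 1/(2n) = 1/2
    assert got[((0, 0), (1, 1))] == pytest.approx(0.5)
    assert got[((0, 1),)] == pytest.approx(0.25)
    assert got[((1, 0),)] == pytest.approx(0.25)
    assert near.key() not in got


def test_jsv_isolated_hole_vertex_feeds_self_proposal():
    g = BipartiteGraph(2, 2, frozenset({(1, 0), (1, 1)}))
    near = MatchingState(g, frozenset({(1, 1)}))  # hole u1 has no edges
    got = proposal_map(jsv_neighbours(near), near)
    assert got[near.key()] == pytest.approx(0.75)
    assert got[((1, 0),)] == pytest.approx(0.25)


def test_jsv_rejects_undersized_state(k22):
    with pytest.raises(InvalidStateError):
        jsv_neighbours(MatchingState(k22, frozenset()))


def test_jsv_weights_k22(k22):
    states = [MatchingState(k22, m) for m in all_matchings(k22)]
    num_perfect, hole_counts, weights = jsv_weights(states)
    assert num_perfect == 2
    assert set(hole_counts.values()) == {1}
    for s, w in zip(states, weights):
        assert w == pytest.approx(1.0 if s.is_perfect else 2.0)
    # each hole class carries the same stationary mass as the perfect class
    mass = {}
    for s, w in zip(states, weights):
        key = "perfect" if s.is_perfect else s.holes()
        mass[key] = mass.get(key, 0.0) + w
    assert all(m == pytest.approx(mass["perfect"]) for m in mass.values())


def test_jsv_weights_require_perfect_matching(path_graph):
    states = [MatchingState(path_graph, frozenset({(0, 0)}))]
    with pytest.raises(UnsupportedInstanceError):
        jsv_weights(states)


# ---------------------------------------------------------------------------
# switch chains
# ---------------------------------------------------------------------------


def test_switch1_two_state_instance():
    state = RealizationState(2, 2, (0b01, 0b10))  # {u1v1, u2v2}
    got = {s.rows: k for s, k in switch1_neighbours(state)}
    assert got[(0b10, 0b01)] == pytest.approx(1.0 / 9.0)
    assert got[state.rows] == pytest.approx(8.0 / 9.0)
    assert len(got) == 2


def test_switch1_dense_two_state_instance():
    seq = DegreeSequencePair((6, 6, 6, 6, 5, 5), (6, 6, 6, 6, 5, 5))
    state = arbitrary_realization(seq)
    proposals = switch1_neighbours(state)
    non_loop = [(s, k) for s, k in proposals if s.rows != state.rows]
    assert len(non_loop) == 1
    assert non_loop[0][1] == pytest.approx(1.0 / 441.0)


def test_switch1_preserves_margins_everywhere(small_switch_pairs):
    for seq in small_switch_pairs:
        for state in margin_matrices(seq):
            for succ, _ in switch1_neighbours(state):
                assert succ.row_sums() == seq.a
                assert succ.col_sums() == seq.b


def test_switch2_two_state_instance():
    state = RealizationState(2, 2, (0b01, 0b10))
    got = {s.rows: k for s, k in switch2_neighbours(state)}
    # pairs of E + artificial edge: {e1,e2}, {e1,u0v0}, {e2,u0v0}
    assert got[(0b10, 0b01)] == pytest.approx(1.0 / 3.0)
    assert got[state.rows] == pytest.approx(2.0 / 3.0)


def test_switch2_all_adjacent_edges_still_well_defined():
    # (1,1);(2): both edges share the single right vertex
    state = RealizationState(2, 1, (0b1, 0b1))
    proposals = switch2_neighbours(state)
    assert len(proposals) == 1
    assert proposals[0][0].rows == state.rows
    assert proposals[0][1] == pytest.approx(1.0)


def test_switch2_never_loopier_than_switch1(small_switch_pairs):
    """The artificial-edge variant is designed to shed loop probability."""
    for seq in small_switch_pairs:
        for state in margin_matrices(seq):
            self1 = sum(
                k for s, k in switch1_neighbours(state) if s.rows == state.rows
            )
            self2 = sum(
                k for s, k in switch2_neighbours(state) if s.rows == state.rows
            )
            assert self2 <= self1 + 1e-12


# ---------------------------------------------------------------------------
# arbitrary-state construction
# ---------------------------------------------------------------------------


def test_arbitrary_realization_identity_margins():
    state = arbitrary_realization(DegreeSequencePair((1, 1), (1, 1)))
    assert sorted(state.edges()) in ([(0, 0), (1, 1)], [(0, 1), (1, 0)])


@pytest.mark.parametrize(
    "a,b", [((2, 2), (1, 1)), ((3, 1), (2, 2))], ids=["sum-mismatch", "overfull-row"]
)
def test_arbitrary_realization_rejects_unrealizable(a, b):
    with pytest.raises(NotRealizableError):
        arbitrary_realization(DegreeSequencePair(a, b))


def test_arbitrary_matching(k22, single_edge, path_graph):
    assert len(arbitrary_matching(k22).matched_edges) == 2
    assert arbitrary_matching(single_edge).matched_edges == frozenset({(0, 0)})
    with pytest.raises(UnsupportedInstanceError):
        arbitrary_matching(path_graph)
    with pytest.raises(UnsupportedInstanceError):
        arbitrary_matching(BipartiteGraph(1, 2, frozenset({(0, 0)})))


# ---------------------------------------------------------------------------
# reachability closures match brute force
# ---------------------------------------------------------------------------


def reachable_keys(chain, instance):
    start = chain.arbitrary_state(instance)
    seen = {chain.state_key(start)}
    stack = [start]
    while stack:
        state = stack.pop()
        for succ, _ in chain.neighbours(state):
            if chain.state_key(succ) not in seen:
                seen.add(chain.state_key(succ))
                stack.append(succ)
    return seen


@pytest.mark.parametrize("n", [1, 2, 3])
def test_broder_reaches_all_matchings(n):
    chain = get_chain("broder")
    for graph in enumerate_bipartite_graphs(n, n, with_perfect_matching_only=True):
        expected = {tuple(sorted(m)) for m in all_matchings(graph)}
        assert reachable_keys(chain, graph) == expected


def test_switch1_reaches_all_realizations(small_switch_pairs):
    chain = get_chain("switch1")
    for seq in small_switch_pairs:
        expected = {m.key() for m in margin_matrices(seq)}
        assert reachable_keys(chain, seq) == expected


# ---------------------------------------------------------------------------
# kappa properties (seeded hypothesis)
# ---------------------------------------------------------------------------


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(min_value=1, max_value=511))
def test_switch_kappa_is_symmetric_and_normalized(bits):
    """kappa(x, y) == kappa(y, x) for both unit-weight switch chains."""
    rows = tuple((bits >> (3 * i)) & 0b111 for i in range(3))
    state = RealizationState(3, 3, rows)
    for neighbours in (switch1_neighbours, switch2_neighbours):
        proposals = neighbours(state)
        assert math.isclose(sum(k for _, k in proposals), 1.0, abs_tol=1e-12)
        for succ, kappa in proposals:
            if succ.rows == state.rows:
                continue
            back = {s.rows: k for s, k in neighbours(succ)}
            assert back[state.rows] == pytest.approx(kappa, abs=1e-12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**9 - 1))
def test_matching_proposals_are_valid_states(bits):
    edges = frozenset(
        (i, j) for i in range(3) for j in range(3) if (bits >> (3 * i + j)) & 1
    )
    graph = BipartiteGraph(3, 3, edges) if edges else None
    if graph is None:
        return
    try:
        start = arbitrary_matching(graph)
    except UnsupportedInstanceError:
        return
    for neighbours in (broder_neighbours, jsv_neighbours):
        for succ, kappa in neighbours(start):
            assert kappa > 0
            succ.validate()


def test_chain_registry():
    assert set(CHAINS) == {"broder", "jsv", "switch1", "switch2"}
    with pytest.raises(KeyError):
        get_chain("nope")
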