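"""Markov-chain transition rules and instance encodings.

The module defines the two instance types (bipartite graphs and bipartite
degree-sequence pairs), the two state types (matchings and realizations),
and four built-in chains:

``broder``
    The matching chain of Broder: pick an edge of the host graph uniformly
    at random and add / remove / slide it.  Unit weights, uniform
    stationary distribution over perfect and near-perfect matchings.
``jsv``
    The weighted matching chain of Jerrum, Sinclair and Vigoda: pick a
    matched edge (perfect state) or a vertex (near-perfect state) and move
    accordingly.  The weight function boosts near-perfect hole classes so
    that each carries the same stationary mass as the perfect class.
``switch1``
    The classical switch chain on bipartite realizations of a degree
    sequence pair: pick index pairs i <= k, j <= l and swap the rectangle
    {u_i,u_k} x {v_j,v_l} when it contains a perfect alternating pattern.
``switch2``
    The loop-reduced switch chain: pick an unordered pair of non-adjacent
    edges of E plus one artificial edge {u0, v0}; pairs involving the
    artificial edge keep the chain aperiodic.

Every chain exposes ``neighbours(state)`` returning a complete proposal
list ``[(successor, kappa), ...]`` in which all random choices leading to
the same successor are aggregated and all "stay" choices are materialised
as one explicit self-proposal, so that kappa sums to one exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import (
    InvalidStateError,
    NotRealizableError,
    UnsupportedInstanceError,
)

KAPPA_TOL = 1e-12

# ---------------------------------------------------------------------------
# instance types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BipartiteGraph:
    """A bipartite graph G = (U, V, E) with |U| = n, |V| = n_prime.

    Edges are stored 0-based as (left index, right index) pairs; file I/O
    is 1-based (u_1..u_n, v_1..v_n').
    """

    n: int
    n_prime: int
    edges: frozenset

    def __post_init__(self):
        object.__setattr__(self, "edges", frozenset(self.edges))
        if self.n < 1 or self.n_prime < 1:
            raise InvalidStateError("vertex counts must be positive")
        for (u, v) in self.edges:
            if not (0 <= u < self.n and 0 <= v < self.n_prime):
                raise InvalidStateError(f"edge ({u},{v}) out of range")

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def degree_left(self, u: int) -> int:
        return sum(1 for (a, _) in self.edges if a == u)

    def to_text(self) -> str:
        """Edge-list serialization: header 'n n_prime', then 1-based pairs."""
        lines = [f"{self.n} {self.n_prime}"]
        for (u, v) in sorted(self.edges):
            lines.append(f"{u + 1} {v + 1}")
        return "\n".join(lines) + "\n"

    @property
    def label(self) -> str:
        body = ",".join(f"{u + 1}-{v + 1}" for (u, v) in sorted(self.edges))
        return f"G{self.n}x{self.n_prime}:{body}"


@dataclass(frozen=True)
class DegreeSequencePair:
    """A pair of non-increasing positive integer sequences (a, b)."""

    a: tuple
    b: tuple

    def __post_init__(self):
        object.__setattr__(self, "a", tuple(int(x) for x in self.a))
        object.__setattr__(self, "b", tuple(int(x) for x in self.b))
        for name, seq in (("a", self.a), ("b", self.b)):
            if len(seq) == 0:
                raise InvalidStateError(f"sequence {name} is empty")
            if any(x < 1 for x in seq):
                raise InvalidStateError(f"sequence {name} has entries < 1")
            if any(seq[i] < seq[i + 1] for i in range(len(seq) - 1)):
                raise InvalidStateError(f"sequence {name} is not non-increasing")

    @property
    def n(self) -> int:
        return len(self.a)

    @property
    def n_prime(self) -> int:
        return len(self.b)

    @property
    def d_max(self) -> int:
        return max(max(self.a), max(self.b))

    def to_text(self) -> str:
        return ",".join(map(str, self.a)) + ";" + ",".join(map(str, self.b))

    label = property(to_text)

    @classmethod
    def from_text(cls, text: str) -> "DegreeSequencePair":
        left, right = text.strip().split(";")
        a = tuple(int(x) for x in left.split(",") if x != "")
        b = tuple(int(x) for x in right.split(",") if x != "")
        return cls(a, b)


def parse_degree_sequence_file(path) -> list:
    """One instance per line, ``a1,a2,...;b1,b2,...``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(DegreeSequencePair.from_text(line))
    return out


def parse_bipartite_graph_file(path) -> BipartiteGraph:
    """Auto-detect edge list (header ``n n'``) vs 0/1 biadjacency matrix."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise InvalidStateError(f"empty graph file {path}")
    first = lines[0].split()
    is_matrix = len(first) == 1 and set(first[0]) <= {"0", "1"} and len(first[0]) > 1
    if is_matrix or (len(first) == 1 and first[0] in ("0", "1") and len(lines) == 1):
        n = len(lines)
        n_prime = len(lines[0])
        edges = set()
        for i, row in enumerate(lines):
            if len(row) != n_prime or set(row) - {"0", "1"}:
                raise InvalidStateError("malformed biadjacency row")
            for j, c in enumerate(row):
                if c == "1":
                    edges.add((i, j))
        return BipartiteGraph(n, n_prime, frozenset(edges))
    n, n_prime = int(first[0]), int(first[1])
    edges = set()
    for ln in lines[1:]:
        u, v = ln.split()
        edges.add((int(u) - 1, int(v) - 1))
    return BipartiteGraph(n, n_prime, frozenset(edges))


# ---------------------------------------------------------------------------
# state types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchingState:
    """A perfect or near-perfect matching of a balanced bipartite host graph."""

    host: BipartiteGraph
    matched_edges: frozenset

    def __post_init__(self):
        object.__setattr__(self, "matched_edges", frozenset(self.matched_edges))

    def validate(self) -> None:
        n = self.host.n
        if self.host.n_prime != n:
            raise InvalidStateError("matching states require n = n'")
        if not self.matched_edges <= self.host.edges:
            raise InvalidStateError("matching uses non-edges of the host")
        lefts = [u for (u, _) in self.matched_edges]
        rights = [v for (_, v) in self.matched_edges]
        if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
            raise InvalidStateError("matching contains adjacent edges")
        if len(self.matched_edges) not in (n - 1, n):
            raise InvalidStateError(
                f"matching size {len(self.matched_edges)} not in {{n-1, n}}"
            )

    @property
    def is_perfect(self) -> bool:
        return len(self.matched_edges) == self.host.n

    def holes(self):
        """The unmatched (left, right) vertex pair of a near-perfect matching."""
        n = self.host.n
        lu = set(range(n)) - {u for (u, _) in self.matched_edges}
        rv = set(range(n)) - {v for (_, v) in self.matched_edges}
        (hu,) = lu
        (hv,) = rv
        return hu, hv

    def key(self):
        """Canonical encoding: the sorted edge tuple."""
        return tuple(sorted(self.matched_edges))

    def __str__(self):
        return "{" + ",".join(f"u{u + 1}v{v + 1}" for (u, v) in self.key()) + "}"


@dataclass(frozen=True)
class RealizationState:
    """A 0/1 biadjacency matrix, stored as one bitmask per row (row-major)."""

    n: int
    n_prime: int
    rows: tuple  # rows[i] has bit j set iff edge (u_i, v_j) present

    @classmethod
    def from_matrix(cls, mat) -> "RealizationState":
        mat = np.asarray(mat)
        n, n_prime = mat.shape
        rows = tuple(
            int(sum(1 << j for j in range(n_prime) if mat[i, j])) for i in range(n)
        )
        return cls(n, n_prime, rows)

    def to_matrix(self) -> np.ndarray:
        out = np.zeros((self.n, self.n_prime), dtype=np.int8)
        for i, r in enumerate(self.rows):
            for j in range(self.n_prime):
                out[i, j] = (r >> j) & 1
        return out

    def has_edge(self, i: int, j: int) -> bool:
        return bool((self.rows[i] >> j) & 1)

    def row_sums(self) -> tuple:
        return tuple(bin(r).count("1") for r in self.rows)

    def col_sums(self) -> tuple:
        return tuple(
            sum((r >> j) & 1 for r in self.rows) for j in range(self.n_prime)
        )

    def edges(self):
        return [
            (i, j)
            for i in range(self.n)
            for j in range(self.n_prime)
            if (self.rows[i] >> j) & 1
        ]

    def packed(self) -> int:
        """Row-major bit packing of the whole matrix into one integer."""
        bits = 0
        for i, r in enumerate(self.rows):
            bits |= r << (i * self.n_prime)
        return bits

    @classmethod
    def from_packed(cls, bits: int, n: int, n_prime: int) -> "RealizationState":
        mask = (1 << n_prime) - 1
        rows = tuple((bits >> (i * n_prime)) & mask for i in range(n))
        return cls(n, n_prime, rows)

    def key(self):
        """Canonical encoding: the row-major bit string."""
        return "".join(
            format(r, f"0{self.n_prime}b")[::-1] for r in self.rows
        )

    def validate_margins(self, seq: DegreeSequencePair) -> None:
        if self.row_sums() != seq.a or self.col_sums() != seq.b:
            raise InvalidStateError("realization margins do not match the sequence")

    def __str__(self):
        return self.key()


# ---------------------------------------------------------------------------
# arbitrary-state construction
# ---------------------------------------------------------------------------


def arbitrary_realization(seq: DegreeSequencePair) -> RealizationState:
    """Greedy Gale-Ryser construction of one realization.

    Row i places its a_i edges on the columns of currently highest residual
    demand (ties broken by lowest column index).  The greedy succeeds
    exactly when the pair is realizable.
    """
    if sum(seq.a) != sum(seq.b):
        raise NotRealizableError(
            f"degree sums differ: {sum(seq.a)} != {sum(seq.b)}"
        )
    residual = list(seq.b)
    rows = []
    for ai in seq.a:
        order = sorted(range(seq.n_prime), key=lambda j: (-residual[j], j))
        chosen = [j for j in order[:ai] if residual[j] > 0]
        if len(chosen) < ai:
            raise NotRealizableError(f"sequence pair {seq.to_text()} not realizable")
        row = 0
        for j in chosen:
            residual[j] -= 1
            row |= 1 << j
        rows.append(row)
    if any(residual):
        raise NotRealizableError(f"sequence pair {seq.to_text()} not realizable")
    return RealizationState(seq.n, seq.n_prime, tuple(rows))


def maximum_matching(graph: BipartiteGraph) -> frozenset:
    """Maximum bipartite matching by augmenting paths (Hungarian scan)."""
    adj = [[] for _ in range(graph.n)]
    for (u, v) in sorted(graph.edges):
        adj[u].append(v)
    match_right = [-1] * graph.n_prime  # right vertex -> left partner

    def try_augment(u, seen):
        for v in adj[u]:
            if v in seen:
                continue
            seen.add(v)
            if match_right[v] == -1 or try_augment(match_right[v], seen):
                match_right[v] = u
                return True
        return False

    for u in range(graph.n):
        try_augment(u, set())
    return frozenset(
        (match_right[v], v) for v in range(graph.n_prime) if match_right[v] != -1
    )


def arbitrary_matching(graph: BipartiteGraph) -> MatchingState:
    """A perfect matching of a balanced host graph, or an error."""
    if graph.n != graph.n_prime:
        raise UnsupportedInstanceError(
            f"matching chains require n = n' (got {graph.n}, {graph.n_prime})"
        )
    m = maximum_matching(graph)
    if len(m) < graph.n:
        raise UnsupportedInstanceError(
            f"graph has no perfect matching (maximum matching size {len(m)})"
        )
    state = MatchingState(graph, m)
    state.validate()
    return state


# ---------------------------------------------------------------------------
# proposal enumeration
# ---------------------------------------------------------------------------


def _aggregate(counter: dict, weight_per_choice: float, self_key, self_count: int):
    """Turn choice counts into an aggregated (state, kappa) proposal list."""
    out = [(state, cnt * weight_per_choice) for state, cnt in counter.values()]
    if self_count:
        out.append((self_key, self_count * weight_per_choice))
    total = sum(k for _, k in out)
    assert abs(total - 1.0) < KAPPA_TOL, f"kappa sums to {total}"
    return out


def broder_neighbours(state: MatchingState):
    """Proposals of the uniform-edge matching chain.

    One edge e = {u, v} of the host is drawn uniformly; depending on the
    current matching it is removed (perfect state), added (both endpoints
    are the holes), or slid along a matched partner edge; all remaining
    draws keep the state.  kappa(M, M') = (#draws producing M') / |E|.
    """
    state.validate()
    host = state.host
    edges = sorted(host.edges)
    if not edges:
        raise UnsupportedInstanceError("host graph has no edges")
    M = state.matched_edges
    proposals: dict = {}
    stay = 0
    if state.is_perfect:
        for e in edges:
            if e in M:
                succ = MatchingState(host, M - {e})
                k = succ.key()
                proposals.setdefault(k, (succ, 0))
                proposals[k] = (succ, proposals[k][1] + 1)
            else:
                stay += 1
    else:
        hu, hv = state.holes()
        right_partner = {v: (u, v) for (u, v) in M}
        left_partner = {u: (u, v) for (u, v) in M}
        for e in edges:
            u, v = e
            if e in M:
                stay += 1
                continue
            if u == hu and v == hv:
                succ = MatchingState(host, M | {e})
            elif u == hu and v in right_partner:
                succ = MatchingState(host, (M - {right_partner[v]}) | {e})
            elif v == hv and u in left_partner:
                succ = MatchingState(host, (M - {left_partner[u]}) | {e})
            else:
                stay += 1
                continue
            k = succ.key()
            proposals.setdefault(k, (succ, 0))
            proposals[k] = (succ, proposals[k][1] + 1)
    return _aggregate(proposals, 1.0 / len(edges), state, stay)


def jsv_neighbours(state: MatchingState):
    """Proposals of the weighted matching chain.

    A perfect matching removes one of its n edges (probability 1/n each).
    A near-perfect matching with holes u, v draws a vertex z uniformly
    from the 2n vertices (probability 1/(2n) each): z in {u, v} adds
    {u, v} when it is an edge (the two draws aggregate to kappa = 1/n);
    any other z slides the matched edge at z towards the hole on the
    opposite side; non-applicable draws keep the state.
    """
    state.validate()
    host = state.host
    n = host.n
    M = state.matched_edges
    proposals: dict = {}

    def put(succ, cnt):
        k = succ.key()
        proposals.setdefault(k, (succ, 0))
        proposals[k] = (succ, proposals[k][1] + cnt)

    if state.is_perfect:
        for e in sorted(M):
            put(MatchingState(host, M - {e}), 1)
        return _aggregate(proposals, 1.0 / n, state, 0)

    hu, hv = state.holes()
    right_partner = {v: (u, v) for (u, v) in M}
    left_partner = {u: (u, v) for (u, v) in M}
    stay = 0
    for z in range(n):  # z in U
        if z == hu:
            if (hu, hv) in host.edges:
                put(MatchingState(host, M | {(hu, hv)}), 1)
            else:
                stay += 1
        elif (z, hv) in host.edges and z in left_partner:
            put(MatchingState(host, (M - {left_partner[z]}) | {(z, hv)}), 1)
        else:
            stay += 1
    for z in range(n):  # z in V
        if z == hv:
            if (hu, hv) in host.edges:
                put(MatchingState(host, M | {(hu, hv)}), 1)
            else:
                stay += 1
        elif (hu, z) in host.edges and z in right_partner:
            put(MatchingState(host, (M - {right_partner[z]}) | {(hu, z)}), 1)
        else:
            stay += 1
    return _aggregate(proposals, 1.0 / (2 * n), state, stay)


def jsv_weights(states: Sequence[MatchingState]):
    """Hole-class boosting weights for the weighted matching chain.

    Given the complete state set (all perfect and near-perfect matchings),
    returns ``(num_perfect, hole_counts, weights)`` where a perfect
    matching has weight 1 and a near-perfect matching with holes (u, v)
    has weight num_perfect / |N_{u,v}|.  Under these weights every hole
    class carries the same total stationary mass as the perfect class.
    """
    num_perfect = sum(1 for s in states if s.is_perfect)
    if num_perfect == 0:
        raise UnsupportedInstanceError("instance has no perfect matching")
    hole_counts: dict = {}
    for s in states:
        if not s.is_perfect:
            hole_counts[s.holes()] = hole_counts.get(s.holes(), 0) + 1
    weights = np.empty(len(states))
    for i, s in enumerate(states):
        weights[i] = 1.0 if s.is_perfect else num_perfect / hole_counts[s.holes()]
    return num_perfect, hole_counts, weights


def switch1_neighbours(state: RealizationState):
    """Proposals of the classical switch chain.

    Four integers i <= k, j <= l are drawn uniformly; when the rectangle
    (i,j),(k,l),(i,l),(k,j) holds a perfect alternating pattern the two
    present edges are switched to the two absent positions.  Every
    non-loop transition has kappa = [2/(n(n+1))] * [2/(n'(n'+1))].
    """
    n, np_ = state.n, state.n_prime
    per_choice = 4.0 / (n * (n + 1) * np_ * (np_ + 1))
    rows = state.rows
    proposals: dict = {}
    stay = 0
    for i in range(n):
        for k in range(i, n):
            for j in range(np_):
                for l in range(j, np_):
                    if i == k or j == l:
                        stay += 1
                        continue
                    ij = (rows[i] >> j) & 1
                    il = (rows[i] >> l) & 1
                    kj = (rows[k] >> j) & 1
                    kl = (rows[k] >> l) & 1
                    if (ij and kl and not il and not kj) or (
                        il and kj and not ij and not kl
                    ):
                        new_rows = list(rows)
                        new_rows[i] ^= (1 << j) | (1 << l)
                        new_rows[k] ^= (1 << j) | (1 << l)
                        succ = RealizationState(n, np_, tuple(new_rows))
                        key = succ.rows
                        proposals.setdefault(key, (succ, 0))
                        proposals[key] = (succ, proposals[key][1] + 1)
                    else:
                        stay += 1
    out = _aggregate(proposals, per_choice, state, stay)
    for succ, _ in out:
        assert succ.row_sums() == state.row_sums(), "switch changed row sums"
        assert succ.col_sums() == state.col_sums(), "switch changed column sums"
    return out


def switch2_neighbours(state: RealizationState):
    """Proposals of the loop-reduced switch chain.

    An unordered pair of non-adjacent edges is drawn uniformly from
    E plus one artificial edge {u0, v0} connecting two extra vertices.
    Pairs containing the artificial edge, and pairs whose switch is
    blocked by an existing edge, keep the state; the remaining pairs
    switch.  The number of non-adjacent pairs is degree-determined, so
    kappa is symmetric and the stationary distribution uniform.
    """
    n, np_ = state.n, state.n_prime
    rows = state.rows
    edges = state.edges()
    m = len(edges)
    # non-adjacent pairs within E
    real_pairs = [
        (e1, e2)
        for idx, e1 in enumerate(edges)
        for e2 in edges[idx + 1 :]
        if e1[0] != e2[0] and e1[1] != e2[1]
    ]
    total_pairs = len(real_pairs) + m  # artificial edge pairs with every real edge
    if total_pairs == 0:
        return [(state, 1.0)]
    per_choice = 1.0 / total_pairs
    proposals: dict = {}
    stay = m  # every artificial-edge pair is a loop
    for (i, j), (k, l) in real_pairs:
        il = (rows[i] >> l) & 1
        kj = (rows[k] >> j) & 1
        if not il and not kj:
            new_rows = list(rows)
            new_rows[i] ^= (1 << j) | (1 << l)
            new_rows[k] ^= (1 << j) | (1 << l)
            succ = RealizationState(n, np_, tuple(new_rows))
            key = succ.rows
            proposals.setdefault(key, (succ, 0))
            proposals[key] = (succ, proposals[key][1] + 1)
        else:
            stay += 1
    return _aggregate(proposals, per_choice, state, stay)


# ---------------------------------------------------------------------------
# chain definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainDefinition:
    """The transition-rule contract consumed by the state-graph scan.

    ``arbitrary_state(instance)`` builds a start state, ``neighbours(state)``
    returns the aggregated proposal list (kappa sums to one, including an
    explicit self-proposal), and ``weights(states)`` assigns the positive
    Metropolis weight of every enumerated state (second pass, so that
    globally-defined weights such as the hole-class counts are available).
    """

    name: str
    arbitrary_state: Callable
    neighbours: Callable
    weights: Callable = field(
        default=lambda states: np.ones(len(states))
    )
    state_key: Callable = field(default=lambda s: s.key())


def _jsv_weight_pass(states):
    return jsv_weights(states)[2]


BRODER = ChainDefinition("broder", arbitrary_matching, broder_neighbours)
JSV = ChainDefinition("jsv", arbitrary_matching, jsv_neighbours, _jsv_weight_pass)
SWITCH1 = ChainDefinition("switch1", arbitrary_realization, switch1_neighbours)
SWITCH2 = ChainDefinition("switch2", arbitrary_realization, switch2_neighbours)

CHAINS = {c.name: c for c in (BRODER, JSV, SWITCH1, SWITCH2)}


def get_chain(name: str) -> ChainDefinition:
    try:
        return CHAINS[name]
    except KeyError:
        raise KeyError(
            f"unknown chain {name!r}; available: {sorted(CHAINS)}"
        ) from None
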