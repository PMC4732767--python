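"""Independent brute-force oracles used across the test suite.

Everything here is deliberately written from first principles (exhaustive
enumeration, step-wise iteration) and never calls the code paths it
checks.
"""

import itertools

import numpy as np

from mixtime.chains import BipartiteGraph, MatchingState, RealizationState


def all_matchings(graph: BipartiteGraph):
    """All perfect and near-perfect matchings, by exhaustive recursion.

    A near-perfect matching of a balanced graph leaves exactly one left
    and one right vertex unmatched, so matching all-but-one left vertex
    injectively enumerates them all.
    """
    n = graph.n
    assert graph.n_prime == n
    adj = {u: sorted(v for (a, v) in graph.edges if a == u) for u in range(n)}
    results = set()

    def assign(lefts, used, chosen):
        if not lefts:
            results.add(frozenset(chosen))
            return
        u = lefts[0]
        for v in adj[u]:
            if v not in used:
                assign(lefts[1:], used | {v}, chosen + [(u, v)])

    assign(list(range(n)), set(), [])  # perfect
    for skip in range(n):  # near-perfect: left vertex `skip` unmatched
        assign([u for u in range(n) if u != skip], set(), [])
    return sorted(results, key=lambda m: tuple(sorted(m)))


def margin_matrices(seq):
    """All 0/1 matrices with row sums seq.a and column sums seq.b."""
    n, m = seq.n, seq.n_prime
    row_options = [
        [sum(1 << j for j in combo) for combo in itertools.combinations(range(m), ai)]
        for ai in seq.a
    ]
    out = []
    for rows in itertools.product(*row_options):
        cols = tuple(sum((r >> j) & 1 for r in rows) for j in range(m))
        if cols == seq.b:
            out.append(RealizationState(n, m, rows))
    return out


def stepwise_tau(P, pi, eps, cap=1 << 20):
    """Plain iterated-multiplication mixing time (no squaring, no search)."""
    P = np.asarray(P, dtype=float)
    M = np.eye(P.shape[0])
    t = 0
    while 0.5 * np.abs(M - pi).sum(axis=1).max() > eps + 1e-12:
        M = M @ P
        t += 1
        assert t <= cap
    return t


def bfs_eccentricities(arcs, n):
    """Shortest-path eccentricity of every node over given directed arcs."""
    adj = [[] for _ in range(n)]
    for (i, j) in arcs:
        adj[i].append(j)
    ecc = []
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        assert len(dist) == n, "disconnected"
        ecc.append(max(dist.values()))
    return ecc
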