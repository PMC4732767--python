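"""Instance enumeration and synthetic fixture generation.

Provides the Gale-Ryser realizability test, exhaustive enumeration of
realizable bipartite degree-sequence pairs up to a size limit, the three
half-regular scaling families, brute-force enumeration of small labelled
bipartite graphs (optionally deduplicated up to row/column permutations),
an exact realization-count dynamic program (used as an independent
cross-check of state-graph sizes for switch chains), and a seeded random
bipartite graph generator.
"""

from __future__ import annotations

import itertools
from collections import Counter
from functools import lru_cache
from math import comb

import numpy as np

from .chains import BipartiteGraph, DegreeSequencePair, maximum_matching
from .errors import CapacityError


def is_realizable(seq: DegreeSequencePair) -> bool:
    """Gale-Ryser test: equal sums and the prefix inequalities."""
    a, b = seq.a, seq.b
    if sum(a) != sum(b):
        return False
    for k in range(1, len(a) + 1):
        if sum(a[:k]) > sum(min(bj, k) for bj in b):
            return False
    return True


def _bounded_partitions(max_len: int, max_part: int):
    """All non-increasing positive sequences with length <= max_len and
    parts <= max_part, as tuples, in lexicographic order."""
    out = []

    def rec(prefix, remaining_len, max_next):
        for part in range(1, max_next + 1):
            seq = prefix + (part,)
            out.append(seq)
            if remaining_len > 1:
                rec(seq, remaining_len - 1, part)

    rec((), max_len, max_part)
    # recursion above emits parts ascending-first; sort sequences properly
    return sorted(set(tuple(sorted(s, reverse=True)) for s in out))


def enumerate_sequence_pairs(
    max_left: int = 6,
    max_right: int = 6,
    ordered: bool = True,
    realizable_only: bool = True,
):
    """Degree-sequence pairs (a, b) within the size box, two conventions.

    Sequences are non-increasing and positive with 1 <= len(a) <= max_left,
    1 <= len(b) <= max_right, parts bounded by the opposite box side, and
    sum(a) = sum(b).  With the defaults only Gale-Ryser-realizable pairs
    are kept and (a, b), (b, a) both appear when distinct -- the form the
    experiment drivers consume, since only realizable instances have a
    state graph.  With ``ordered=False`` each unordered pair {a, b} is
    emitted once (as its lexicographically smaller ordering); with
    ``realizable_only=False`` the Gale-Ryser filter is dropped.  The
    unordered, unfiltered convention is the one whose 6+6 count matches
    the instance census of the original enumeration study (19,378); the
    ordered realizable census at 6+6 is 15,583.  Output is deterministic,
    duplicate-free, sorted lexicographically by (a, b).
    """
    # realizability forces every a_i <= len(b) <= max_right and vice versa
    left_seqs = _bounded_partitions(max_left, max_right)
    right_seqs = _bounded_partitions(max_right, max_left)
    by_sum: dict = {}
    for b in right_seqs:
        by_sum.setdefault(sum(b), []).append(b)
    pairs = []
    for a in left_seqs:
        for b in by_sum.get(sum(a), ()):
            if not ordered and b < a:
                continue
            seq = DegreeSequencePair(a, b)
            if realizable_only and not is_realizable(seq):
                continue
            pairs.append(seq)
    pairs.sort(key=lambda s: (s.a, s.b))
    return pairs


def count_realizations(seq: DegreeSequencePair) -> int:
    """Exact number of 0/1 matrices with row sums a and column sums b.

    Column-by-column dynamic program over the multiset of residual row
    demands: for each column, its ones are distributed over residual
    classes with binomial multiplicities.  Independent of any switch-chain
    reachability argument, so it serves as a cross-oracle for switch-chain
    state-graph sizes.
    """
    a, b = seq.a, seq.b
    if sum(a) != sum(b):
        return 0
    cols = tuple(sorted(b, reverse=True))

    @lru_cache(maxsize=None)
    def rec(residuals: tuple, ci: int) -> int:
        remaining = len(cols) - ci
        if max(residuals, default=0) > remaining:
            return 0
        if ci == len(cols):
            return 1 if not residuals or max(residuals) == 0 else 0
        need = cols[ci]
        counts = sorted(Counter(r for r in residuals if r > 0).items())
        values = [v for v, _ in counts]
        avail = [c for _, c in counts]
        zeros = sum(1 for r in residuals if r == 0)
        total = 0

        def place(idx, left, ways, taken):
            nonlocal total
            if left == 0:
                taken = taken + (0,) * (len(counts) - len(taken))
                new = [0] * zeros
                for (v, c), t in zip(counts, taken):
                    new.extend([v] * (c - t))
                    new.extend([v - 1] * t)
                total += ways * rec(tuple(sorted(new)), ci + 1)
                return
            if idx == len(values):
                return
            for t in range(min(avail[idx], left) + 1):
                place(idx + 1, left - t, ways * comb(avail[idx], t), taken + (t,))

        place(0, need, 1, ())
        return total

    return rec(tuple(sorted(a)), 0)


def scaling_sequence(family: str, n: int) -> DegreeSequencePair:
    """Half-regular scaling families A, B, C.

    A: (n-1, n-2, 2, 1) vs n twos (n >= 4)
    B: (n-1, n-2, 3)    vs n twos (n >= 3)
    C: (n-1, n-2, 1, 1, 1) vs n twos (n >= 4)

    The first sequence is returned sorted non-increasing; the second is
    the constant sequence (2, ..., 2) of length n, which makes every
    family half-regular.
    """
    family = family.upper()
    minima = {"A": 4, "B": 3, "C": 4}
    if family not in minima:
        raise ValueError(f"unknown scaling family {family!r}")
    if n < minima[family]:
        raise ValueError(f"family {family} requires n >= {minima[family]}")
    if family == "A":
        a = (n - 1, n - 2, 2, 1)
    elif family == "B":
        a = (n - 1, n - 2, 3)
    else:
        a = (n - 1, n - 2, 1, 1, 1)
    return DegreeSequencePair(tuple(sorted(a, reverse=True)), (2,) * n)


# ---------------------------------------------------------------------------
# small bipartite graphs (matching-chain fixtures)
# ---------------------------------------------------------------------------

_BRUTE_FORCE_CAP = 4


def _is_connected(n, n_prime, edges) -> bool:
    """Connectivity of the full vertex set (isolated vertices disconnect)."""
    if not edges:
        return n + n_prime == 1
    parent = list(range(n + n_prime))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (u, v) in edges:
        ru, rv = find(u), find(n + v)
        parent[ru] = rv
    return len({find(x) for x in range(n + n_prime)}) == 1


def _has_perfect_matching(graph: BipartiteGraph) -> bool:
    return graph.n == graph.n_prime and len(maximum_matching(graph)) == graph.n


def _canonical_form(rows, n_prime):
    """Minimal row-sorted representation over all column permutations.

    A canonical form under independent row and column permutations:
    for each column order, permute every row's bits and sort the rows;
    take the lexicographically smallest result.
    """
    best = None
    for perm in itertools.permutations(range(n_prime)):
        permuted = tuple(
            sorted(
                sum(((r >> j) & 1) << pj for pj, j in enumerate(perm))
                for r in rows
            )
        )
        if best is None or permuted < best:
            best = permuted
    return best


def enumerate_bipartite_graphs(
    n: int,
    n_prime: int,
    connected_only: bool = False,
    with_perfect_matching_only: bool = False,
    dedup_isomorphic: bool = False,
):
    """All labelled bipartite graphs on n + n' vertices meeting the filters.

    Brute force over all 2^(n*n') biadjacency matrices; capped at 4+4.
    With ``dedup_isomorphic`` one representative per row/column-permutation
    class is kept (smallest canonical form).
    """
    if n > _BRUTE_FORCE_CAP or n_prime > _BRUTE_FORCE_CAP:
        raise CapacityError(
            f"brute-force graph enumeration capped at {_BRUTE_FORCE_CAP}+"
            f"{_BRUTE_FORCE_CAP}; larger sets require isomorph-free generation "
            "tooling outside this package"
        )
    out = []
    seen = set()
    mask = (1 << n_prime) - 1
    for bits in range(1 << (n * n_prime)):
        rows = tuple((bits >> (i * n_prime)) & mask for i in range(n))
        edges = frozenset(
            (i, j) for i in range(n) for j in range(n_prime) if (rows[i] >> j) & 1
        )
        if connected_only and not _is_connected(n, n_prime, edges):
            continue
        graph = BipartiteGraph(n, n_prime, edges)
        if with_perfect_matching_only and not _has_perfect_matching(graph):
            continue
        if dedup_isomorphic:
            canon = _canonical_form(rows, n_prime)
            if canon in seen:
                continue
            seen.add(canon)
        out.append(graph)
    return out


def random_bipartite_graph(
    n: int, n_prime: int, edge_prob: float, seed: int
) -> BipartiteGraph:
    """Erdos-Renyi-style bipartite graph: each of the n*n' possible edges is
    included independently with probability ``edge_prob`` under a seeded
    numpy PCG64 generator."""
    if not (0 < edge_prob <= 1):
        raise ValueError("edge_prob must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random((n, n_prime))
    edges = frozenset(
        (i, j) for i in range(n) for j in range(n_prime) if draws[i, j] < edge_prob
    )
    return BipartiteGraph(n, n_prime, edges)
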