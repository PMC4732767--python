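"""Bit-packed breadth-first scan for switch-chain state graphs.

States of the classical switch chain on an n x n' degree-sequence pair are
0/1 matrices with fixed margins; with n*n' <= 63 a state packs into one
int64 (row-major bits).  A switch toggles the four corners of a rectangle
{i,k} x {j,l} whenever exactly one diagonal of the rectangle is present,
so the whole neighbourhood structure is expressible with three precomputed
bit tables (corner mask and the two diagonal patterns) and the scan
reduces to integer arithmetic.  The kernels are JIT-compiled with numba
when available; the identical pure-Python path is kept both as a fallback
and as a correctness reference in the tests.

Only the classical switch chain gets this treatment: its kappa is a single
constant per non-loop arc, so adjacency alone determines the transition
matrix.
"""

from __future__ import annotations

import numpy as np

from .chains import DegreeSequencePair, arbitrary_realization

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def rectangle_tables(n: int, n_prime: int):
    """Bit tables for all rectangles i<k, j<l of an n x n' matrix.

    Returns (mask4, diag1, diag2): the four-corner mask and the two
    two-corner diagonal patterns.  A state ``s`` has a switch on the
    rectangle iff ``s & mask4`` equals one of the diagonals; the successor
    is ``s ^ mask4``.
    """
    mask4, diag1, diag2 = [], [], []
    for i in range(n):
        for k in range(i + 1, n):
            for j in range(n_prime):
                for l in range(j + 1, n_prime):
                    bij = 1 << (i * n_prime + j)
                    bil = 1 << (i * n_prime + l)
                    bkj = 1 << (k * n_prime + j)
                    bkl = 1 << (k * n_prime + l)
                    mask4.append(bij | bil | bkj | bkl)
                    diag1.append(bij | bkl)
                    diag2.append(bil | bkj)
    return (
        np.asarray(mask4, dtype=np.int64),
        np.asarray(diag1, dtype=np.int64),
        np.asarray(diag2, dtype=np.int64),
    )


def _scan_py(start, mask4, diag1, diag2, max_states, collect_edges):
    """Reference implementation of the packed scan (dict + FIFO)."""
    index = {start: 0}
    order = [start]
    src, dst = [], []
    head = 0
    while head < len(order):
        s = order[head]
        si = index[s]
        head += 1
        for r in range(len(mask4)):
            window = s & mask4[r]
            if window == diag1[r] or window == diag2[r]:
                t = s ^ mask4[r]
                ti = index.get(t)
                if ti is None:
                    if max_states and len(order) >= max_states:
                        return None
                    ti = len(order)
                    index[t] = ti
                    order.append(t)
                if collect_edges:
                    src.append(si)
                    dst.append(ti)
    return (
        np.asarray(order, dtype=np.int64),
        np.asarray(src, dtype=np.int64),
        np.asarray(dst, dtype=np.int64),
    )


if HAVE_NUMBA:
    from numba.typed import Dict as _NbDict, List as _NbList
    from numba.types import int64 as _nb_i64

    @numba.njit(cache=True)
    def _scan_nb(start, mask4, diag1, diag2, max_states, collect_edges):
        index = _NbDict.empty(key_type=_nb_i64, value_type=_nb_i64)
        index[start] = 0
        order = _NbList.empty_list(_nb_i64)
        order.append(start)
        src = _NbList.empty_list(_nb_i64)
        dst = _NbList.empty_list(_nb_i64)
        head = 0
        nrect = mask4.shape[0]
        while head < len(order):
            s = order[head]
            si = index[s]
            head += 1
            for r in range(nrect):
                window = s & mask4[r]
                if window == diag1[r] or window == diag2[r]:
                    t = s ^ mask4[r]
                    if t in index:
                        ti = index[t]
                    else:
                        if max_states > 0 and len(order) >= max_states:
                            return (
                                np.empty(0, dtype=np.int64),
                                np.empty(0, dtype=np.int64),
                                np.empty(0, dtype=np.int64),
                                False,
                            )
                        ti = np.int64(len(order))
                        index[t] = ti
                        order.append(t)
                    if collect_edges:
                        src.append(si)
                        dst.append(ti)
        states = np.empty(len(order), dtype=np.int64)
        for i in range(len(order)):
            states[i] = order[i]
        src_a = np.empty(len(src), dtype=np.int64)
        dst_a = np.empty(len(dst), dtype=np.int64)
        for i in range(len(src)):
            src_a[i] = src[i]
            dst_a[i] = dst[i]
        return states, src_a, dst_a, True


def packed_switch_scan(
    seq: DegreeSequencePair,
    max_states: int = 0,
    collect_edges: bool = True,
    force_python: bool = False,
):
    """Enumerate the switch-chain component of a degree-sequence pair.

    Returns ``(states, src, dst)``: the packed states in discovery order
    and the directed non-loop arc list (each unordered switch appears in
    both directions because the scan visits both endpoints).  ``max_states``
    of 0 means unlimited; when exceeded, None is returned.  With
    ``collect_edges`` False the arc arrays are empty (state counting only).
    """
    if seq.n * seq.n_prime > 63:
        raise ValueError("packed scan limited to n * n' <= 63 bits")
    start = np.int64(arbitrary_realization(seq).packed())
    mask4, diag1, diag2 = rectangle_tables(seq.n, seq.n_prime)
    if HAVE_NUMBA and not force_python:
        states, src, dst, ok = _scan_nb(
            start, mask4, diag1, diag2, np.int64(max_states), collect_edges
        )
        if not ok:
            return None
        return states, src, dst
    return _scan_py(
        int(start), mask4, diag1, diag2, int(max_states), collect_edges
    )


def switch_state_count(seq: DegreeSequencePair) -> int:
    """Number of realizations reachable from the greedy start by switches."""
    states, _, _ = packed_switch_scan(seq, max_states=0, collect_edges=False)
    return int(states.shape[0])


def switch_transition_matrix(seq: DegreeSequencePair, max_states: int = 0):
    """Dense transition matrix of the classical switch chain.

    Every non-loop arc carries the constant proposal probability
    kappa = [2/(n(n+1))] * [2/(n'(n'+1))]; the diagonal absorbs the rest.
    Returns ``(states, P)`` or None when ``max_states`` is exceeded.
    """
    scan = packed_switch_scan(seq, max_states=max_states, collect_edges=True)
    if scan is None:
        return None
    states, src, dst = scan
    n, np_ = seq.n, seq.n_prime
    kappa = 4.0 / (n * (n + 1) * np_ * (np_ + 1))
    size = states.shape[0]
    P = np.zeros((size, size))
    np.add.at(P, (src, dst), kappa)
    P[np.arange(size), np.arange(size)] += 1.0 - P.sum(axis=1)
    return states, P
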