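"""Exact total mixing time via matrix squaring plus binary search.

The total variation distance of the walk from every start state after t
steps is read off the rows of P^t; its maximum over rows, d(t), decreases
monotonically in t, so tau(eps) = min{t : d(t) <= eps} can be located by
(1) repeated squaring of P until d(2^i) <= eps, then (2) binary search on
the bracket (2^(i-1), 2^i], reusing P^l and the stored powers P^(2^k) so
that every probe costs one matrix product.  A step-wise oracle
(:func:`total_mixing_time_bruteforce`) recomputes tau by plain iteration
and is used throughout the test suite to validate the fast path.

Comparisons with eps are `<=` with an absolute slack of 1e-12 to absorb
accumulation error from repeated multiplication; both the fast path and
the oracle apply the same rule, keeping them exactly consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import CapacityError, NonErgodicError

EPS_SLACK = 1e-12
DEFAULT_EXPONENT_CAP = 60
BRUTEFORCE_STATE_CAP = 20000


def total_variation(mu, eta) -> float:
    """Half the L1 distance between two probability distributions."""
    mu = np.asarray(mu, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if mu.shape != eta.shape:
        raise ValueError(f"length mismatch: {mu.shape} vs {eta.shape}")
    return 0.5 * float(np.abs(mu - eta).sum())


def _as_dense(P) -> np.ndarray:
    return P.toarray() if sp.issparse(P) else np.asarray(P, dtype=float)


def _max_tv(M: np.ndarray, pi: np.ndarray) -> float:
    """max over rows a of || M[a, :] - pi ||_TV."""
    return 0.5 * float(np.abs(M - pi).sum(axis=1).max())


def assert_ergodic(P, pi) -> None:
    """Refuse disconnected, periodic, or non-reversible inputs."""
    P = _as_dense(P)
    n = P.shape[0]
    if n == 1:
        return
    mask = (P > 0).astype(np.int8)
    np.fill_diagonal(mask, 0)
    ncomp, _ = connected_components(
        sp.csr_matrix(mask), directed=True, connection="strong"
    )
    if ncomp != 1:
        raise NonErgodicError("state graph is not strongly connected")
    if not np.any(np.diag(P) > 0):
        g = nx.Graph(
            (int(i), int(j)) for i, j in zip(*np.nonzero(mask))
        )
        if nx.is_bipartite(g):
            raise NonErgodicError("chain is periodic (loop-free bipartite graph)")
    residual = float(np.max(np.abs(pi[:, None] * P - (pi[:, None] * P).T)))
    if residual > 1e-10:
        raise NonErgodicError(f"chain not reversible (residual {residual:.3e})")


def max_tv_at_step(P, pi, t: int) -> float:
    """d(t): the worst-start total variation distance after t steps."""
    assert_ergodic(P, pi)
    if t < 0:
        raise ValueError("t must be non-negative")
    P = _as_dense(P)
    pi = np.asarray(pi, dtype=float)
    M = np.eye(P.shape[0])
    base = P.copy()
    k = t
    while k:  # binary exponentiation
        if k & 1:
            M = M @ base
        k >>= 1
        if k:
            base = base @ base
    return _max_tv(M, pi)


@dataclass
class MixingResult:
    """tau(eps) with the algorithm trace."""

    tau: int
    epsilon: float
    per_state: Optional[np.ndarray] = None
    trace: dict = field(default_factory=dict)


def total_mixing_time(
    P, pi, epsilon: float, exponent_cap: int = DEFAULT_EXPONENT_CAP
) -> MixingResult:
    """Least t with max_a ||p_a^(t) - pi|| <= eps, by squaring + bisection.

    Phase 1 squares P until d(2^i) <= eps, storing every power P^(2^k).
    Phase 2 maintains the bracket invariant d(l) > eps >= d(r) on
    (l, r] = (2^(i-1), 2^i] and halves it with single products
    P^m = P^l P^(m-l), m - l a stored power of two.  The result equals
    the step-wise oracle exactly.
    """
    assert_ergodic(P, pi)
    if not (0 < epsilon < 1):
        raise ValueError("epsilon must lie in (0, 1)")
    P = _as_dense(P)
    pi = np.asarray(pi, dtype=float)
    trace: dict = {"squarings": [], "bisection": []}
    d0 = _max_tv(np.eye(P.shape[0]), pi)
    if d0 <= epsilon + EPS_SLACK:
        return MixingResult(0, epsilon, trace=trace)
    powers = [P]  # powers[k] = P^(2^k)
    i = 0
    while _max_tv(powers[-1], pi) > epsilon + EPS_SLACK:
        i += 1
        if i > exponent_cap:
            raise CapacityError(
                f"no mixing below 2^{exponent_cap} steps (effectively non-mixing)"
            )
        powers.append(powers[-1] @ powers[-1])
        trace["squarings"].append(i)
    if i == 0:
        return MixingResult(1, epsilon, trace=trace)
    l, r = 1 << (i - 1), 1 << i
    Pl = powers[i - 1]
    while r - l > 1:
        step = (r - l) >> 1
        m = l + step
        Pm = Pl @ powers[step.bit_length() - 1]
        if _max_tv(Pm, pi) <= epsilon + EPS_SLACK:
            r = m
        else:
            l, Pl = m, Pm
        trace["bisection"].append((l, r))
    return MixingResult(r, epsilon, trace=trace)


def total_mixing_time_bruteforce(
    P, pi, epsilon: float, max_steps: int = 1 << 22
) -> int:
    """Step-wise oracle: iterate P^(t+1) = P^t P for all starts at once."""
    assert_ergodic(P, pi)
    P = _as_dense(P)
    if P.shape[0] > BRUTEFORCE_STATE_CAP:
        raise CapacityError("brute-force oracle limited to small state graphs")
    pi = np.asarray(pi, dtype=float)
    M = np.eye(P.shape[0])
    t = 0
    while _max_tv(M, pi) > epsilon + EPS_SLACK:
        M = M @ P
        t += 1
        if t > max_steps:
            raise CapacityError(f"no mixing within {max_steps} steps")
    return t


def per_state_mixing_time(P, pi, epsilon: float, a: int, max_steps: int = 1 << 22) -> int:
    """tau_a(eps): least t with ||p_a^(t) - pi|| <= eps from start state a."""
    assert_ergodic(P, pi)
    P = _as_dense(P)
    pi = np.asarray(pi, dtype=float)
    p = np.zeros(P.shape[0])
    p[a] = 1.0
    t = 0
    while total_variation(p, pi) > epsilon + EPS_SLACK:
        p = p @ P
        t += 1
        if t > max_steps:
            raise CapacityError(f"no mixing within {max_steps} steps")
    return t
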