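"""Spectral and canonical-path (congestion) mixing-time bounds.

For a reversible chain the symmetrized matrix
P_sym = D^{1/2} P D^{-1/2} (D = diag(pi)) shares the spectrum of P;
with lambda_max = max(|lambda_2|, |lambda_min|) the total mixing time is
bracketed by

    lower = 1/2 * lambda_max / (1 - lambda_max) * ln(1/(2 eps))
    upper = 1 / (1 - lambda_max) * (ln(1/eps) + ln(1/pi_min)).

The canonical-path method routes one simple path per ordered state pair
(x, y); each non-loop arc of a path accumulates load |p| pi(x) pi(y),
the maximum load congestion rho is the largest arc total divided by
pi(u) P(u, v), and rho * (ln(1/eps) + ln(1/pi_min)) is another upper
bound.  The path-construction scheme is pluggable; the built-in default
routes along deterministic BFS shortest paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import MixtimeError, NonErgodicError, NonReversibleError
from .stategraph import StateGraph, detailed_balance_residual

DENSE_EIG_LIMIT = 500
SPARSE_EIG_TOL = 1e-10


def symmetrize(P, pi):
    """D^{1/2} P D^{-1/2}; symmetric exactly when detailed balance holds."""
    residual = detailed_balance_residual(P, pi)
    if residual > 1e-10:
        raise NonReversibleError(residual)
    pi = np.asarray(pi, dtype=float)
    s = np.sqrt(pi)
    if sp.issparse(P):
        return sp.diags(s) @ P @ sp.diags(1.0 / s)
    return s[:, None] * np.asarray(P) / s[None, :]


def _dense_extremes(P_sym: np.ndarray):
    vals = np.linalg.eigvalsh((P_sym + P_sym.T) / 2.0)
    return float(vals[-2]), float(vals[0])  # lambda_2, lambda_min


def _sparse_extremes(P_sym, tol=SPARSE_EIG_TOL):
    n = P_sym.shape[0]
    maxiter = 10 * n
    top = spla.eigsh(
        P_sym, k=2, which="LA", tol=tol, maxiter=maxiter, return_eigenvectors=False
    )
    bottom = spla.eigsh(
        P_sym, k=1, which="SA", tol=tol, maxiter=maxiter, return_eigenvectors=False
    )
    return float(np.sort(top)[0]), float(bottom[0])


def eigen_extremes(P_sym):
    """(lambda_2, lambda_min) of the symmetrized matrix.

    Dense solver below 500 states; Lanczos (ARPACK) above, with a dense
    fallback on non-convergence.
    """
    n = P_sym.shape[0]
    if n == 1:
        return 0.0, 0.0
    if n == 2 or (not sp.issparse(P_sym) and n <= DENSE_EIG_LIMIT):
        return _dense_extremes(
            P_sym.toarray() if sp.issparse(P_sym) else np.asarray(P_sym)
        )
    if sp.issparse(P_sym) and n <= DENSE_EIG_LIMIT:
        return _dense_extremes(P_sym.toarray())
    try:
        return _sparse_extremes(P_sym)
    except spla.ArpackNoConvergence as exc:  # pragma: no cover - rare
        if P_sym.shape[0] <= 20000:
            return _dense_extremes(
                P_sym.toarray() if sp.issparse(P_sym) else np.asarray(P_sym)
            )
        raise MixtimeError(
            f"eigensolver failed to converge: {exc}"
        ) from exc


def lambda_max_mag(P_sym) -> float:
    """max(|lambda_2|, |lambda_min|): largest non-Perron eigenvalue magnitude."""
    lam2, lam_min = eigen_extremes(P_sym)
    return max(abs(lam2), abs(lam_min))


def spectral_bounds(lambda_max: float, pi_min: float, epsilon: float):
    """(lower, upper) spectral mixing-time bounds."""
    if not (0 < epsilon < 1):
        raise ValueError("epsilon must lie in (0, 1)")
    if not (0 < pi_min <= 1):
        raise ValueError("pi_min must lie in (0, 1]")
    if lambda_max >= 1.0 - 1e-12:
        raise NonErgodicError("lambda_max >= 1: chain does not mix")
    lower = 0.5 * lambda_max / (1.0 - lambda_max) * np.log(1.0 / (2.0 * epsilon))
    upper = (np.log(1.0 / epsilon) + np.log(1.0 / pi_min)) / (1.0 - lambda_max)
    return float(lower), float(upper)


@dataclass(frozen=True)
class SpectralReport:
    lambda2: float
    lambda_min: float
    lambda_max_mag: float
    pi_min: float
    lower: float
    upper: float


def spectral_report(graph: StateGraph, epsilon: float) -> SpectralReport:
    """Full spectral analysis of a finalized state graph."""
    P_sym = symmetrize(graph.P, graph.pi)
    lam2, lam_min = eigen_extremes(P_sym)
    lam = max(abs(lam2), abs(lam_min))
    pi_min = float(graph.pi.min())
    lower, upper = spectral_bounds(lam, pi_min, epsilon)
    return SpectralReport(lam2, lam_min, lam, pi_min, lower, upper)


# ---------------------------------------------------------------------------
# canonical paths
# ---------------------------------------------------------------------------


class PathSystem:
    """One simple path per ordered state pair, stored as BFS parent arrays.

    The default construction is deterministic: distances by BFS over the
    non-loop arcs, and each state's predecessor is the smallest-index
    in-neighbour one level closer to the source.  ``path(x, y)`` returns
    the state sequence from x to y.
    """

    def __init__(self, parents: dict, num_states: int):
        self._parents = parents  # source -> parent array
        self.num_states = num_states

    def path(self, x: int, y: int):
        parent = self._parents[x]
        if parent[y] < 0 and y != x:
            raise MixtimeError(f"no path from {x} to {y}")
        out = [y]
        while out[-1] != x:
            out.append(parent[out[-1]])
        out.reverse()
        return out

    def pairs(self):
        for x in range(self.num_states):
            for y in range(self.num_states):
                if x != y:
                    yield x, y


def shortest_path_system(graph: StateGraph) -> PathSystem:
    """Deterministic BFS shortest paths between all ordered state pairs."""
    n = graph.num_states
    succ = [sorted(j for j in row if j != i) for i, row in enumerate(graph.kappa)]
    pred = [[] for _ in range(n)]
    for i, out in enumerate(succ):
        for j in out:
            pred[j].append(i)
    parents = {}
    for x in range(n):
        dist = np.full(n, -1, dtype=np.int64)
        parent = np.full(n, -1, dtype=np.int64)
        dist[x] = 0
        frontier = [x]
        while frontier:
            nxt = []
            for u in frontier:
                for v in succ[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for y in range(n):
            if y == x or dist[y] < 0:
                continue
            parent[y] = min(
                u for u in pred[y] if dist[u] == dist[y] - 1
            )
        if np.any((dist < 0) & (np.arange(n) != x)):
            raise NonErgodicError("state graph is disconnected: no path system")
        parents[x] = parent
    return PathSystem(parents, n)


PATH_SCHEMES: dict = {"shortest-path": shortest_path_system}


def register_path_scheme(name: str, builder: Callable) -> None:
    """Register a custom scheme: ``builder(graph) -> PathSystem``-like object
    exposing ``path(x, y)`` and ``pairs()``."""
    PATH_SCHEMES[name] = builder


@dataclass(frozen=True)
class CongestionReport:
    rho: float
    argmax_arc: tuple
    bound: float


def congestion(
    graph: StateGraph, path_system, epsilon: float
) -> CongestionReport:
    """Maximum load congestion rho and the induced mixing-time bound.

    Every ordered pair (x, y), x != y, routes pi(x) pi(y) |p| along each
    non-loop arc of its path; each arc total is divided by pi(u) P(u, v);
    rho is the maximum and the bound rho (ln 1/eps + ln 1/pi_min).
    Accumulation is a plain sum, so the result is independent of pair
    order up to floating-point roundoff.
    """
    pi = graph.pi
    P = graph.P
    arc_index = {(i, j): None for i, j in graph.nonloop_arcs()}
    load: dict = {arc: 0.0 for arc in arc_index}
    for x, y in path_system.pairs():
        p = path_system.path(x, y)
        contrib = (len(p) - 1) * pi[x] * pi[y]
        for u, v in zip(p[:-1], p[1:]):
            if (u, v) not in load:
                raise MixtimeError(f"path system uses non-arc ({u}, {v})")
            load[(u, v)] += contrib
    rho, argmax = 0.0, None
    for (u, v), total in load.items():
        puv = P[u, v] if not sp.issparse(P) else P[u, v]
        denom = pi[u] * float(puv)
        if denom <= 0:
            raise MixtimeError(f"arc ({u}, {v}) has zero flow capacity")
        value = total / denom
        if value > rho:
            rho, argmax = value, (u, v)
    pi_min = float(pi.min())
    bound = rho * (np.log(1.0 / epsilon) + np.log(1.0 / pi_min))
    return CongestionReport(rho, argmax, float(bound))
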