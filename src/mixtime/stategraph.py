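"""State-graph enumeration, Metropolis finalization, and network metrics.

A :class:`StateGraph` holds the complete reachable state set of one
(chain, instance) pair: the canonical states Omega, the proposal arcs Psi
with their probabilities kappa, the Metropolis transition matrix P and the
stationary distribution pi.  The scan starts from the chain's arbitrary
state and closes the set under the chain's proposal rule; the Metropolis
rule P(u, v) = kappa(u, v) * min(1, w(v)/w(u)) is applied in a second
pass once all states (and hence globally-defined weights) are known.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .chains import ChainDefinition
from .errors import CapacityError, MixtimeError, NonErgodicError

DENSE_LIMIT = 500  # dense transition matrix below, CSR sparse above

ROW_SUM_TOL = 1e-10
BALANCE_TOL = 1e-10
PI_TOL = 1e-12


@dataclass
class StateGraph:
    """The explicit state graph Gamma = (Omega, Psi) of one chain instance."""

    states: list
    index: dict
    kappa: list  # kappa[i] = {j: proposal probability}, self-loops included
    chain_name: str
    instance_label: str
    weights: Optional[np.ndarray] = None
    P: Optional[object] = None  # dense ndarray or scipy CSR
    pi: Optional[np.ndarray] = None

    @property
    def num_states(self) -> int:
        return len(self.states)

    @property
    def num_arcs(self) -> int:
        """Number of proposal arcs (self-loops included)."""
        return sum(len(row) for row in self.kappa)

    def dense_P(self) -> np.ndarray:
        if self.P is None:
            raise MixtimeError("transition matrix not finalized")
        return self.P.toarray() if sp.issparse(self.P) else np.asarray(self.P)

    def loop_probabilities(self) -> np.ndarray:
        P = self.P
        return P.diagonal() if sp.issparse(P) else np.diag(P).copy()

    def nonloop_arcs(self):
        for i, row in enumerate(self.kappa):
            for j in row:
                if j != i:
                    yield i, j


def construct_state_graph(
    chain: ChainDefinition, instance, max_states: Optional[int] = 20000
) -> StateGraph:
    """Full graph scan: close the arbitrary start state under ``neighbours``.

    Arcs carry the proposal probabilities kappa (the explicit self-proposal
    is stored on the diagonal).  ``max_states`` aborts oversized scans with
    a :class:`CapacityError`; pass None for no cap.
    """
    start = chain.arbitrary_state(instance)
    key = chain.state_key
    index = {key(start): 0}
    states = [start]
    kappa: list = []
    queue = deque([0])
    while queue:
        i = queue.popleft()
        row: dict = {}
        for succ, k in chain.neighbours(states[i]):
            sk = key(succ)
            j = index.get(sk)
            if j is None:
                if max_states is not None and len(states) >= max_states:
                    raise CapacityError(
                        f"state cap {max_states} exceeded while scanning "
                        f"{chain.name} on {getattr(instance, 'label', instance)} "
                        f"(reached {len(states)} states)"
                    )
                j = len(states)
                index[sk] = j
                states.append(succ)
                queue.append(j)
            row[j] = row.get(j, 0.0) + k
        kappa.append(row)
    # rows are appended in pop order == index order because the queue is FIFO
    assert len(kappa) == len(states)
    return StateGraph(
        states=states,
        index=index,
        kappa=kappa,
        chain_name=chain.name,
        instance_label=str(getattr(instance, "label", instance)),
    )


def finalize_transitions(
    graph: StateGraph, weight_fn: Optional[Callable] = None
) -> StateGraph:
    """Apply the Metropolis rule and set the stationary distribution.

    P(u, v) = kappa(u, v) * min(1, w(v)/w(u)) for u != v; the rejected
    proposal mass joins the self-loop so each row sums to one; pi = w / sum w.
    ``weight_fn`` maps the full state list to a positive weight vector
    (defaults to unit weights).
    """
    n = graph.num_states
    if weight_fn is None:
        w = np.ones(n)
    else:
        w = np.asarray(weight_fn(graph.states), dtype=float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ValueError("weights must be a positive vector over all states")
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for i, row in enumerate(graph.kappa):
        off = 0.0
        for j, k in row.items():
            if j == i:
                continue
            p = k * min(1.0, w[j] / w[i])
            rows.append(i)
            cols.append(j)
            vals.append(p)
            off += p
        diag[i] = 1.0 - off
    for i in range(n):
        rows.append(i)
        cols.append(i)
        vals.append(diag[i])
    if n <= DENSE_LIMIT:
        P = np.zeros((n, n))
        np.add.at(P, (rows, cols), vals)
    else:
        P = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        P.sum_duplicates()
    pi = w / w.sum()
    out = replace(graph, weights=w, P=P, pi=pi)
    _assert_finalized_invariants(out)
    return out


def _assert_finalized_invariants(graph: StateGraph) -> None:
    P, pi = graph.P, graph.pi
    row_sums = np.asarray(P.sum(axis=1)).ravel()
    if np.max(np.abs(row_sums - 1.0)) > ROW_SUM_TOL:
        raise MixtimeError("transition rows do not sum to one")
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > PI_TOL:
        raise MixtimeError("stationary vector invalid")
    if detailed_balance_residual(P, pi) > BALANCE_TOL:
        raise MixtimeError("detailed balance violated after finalization")


def detailed_balance_residual(P, pi) -> float:
    """max_{i,j} |pi_i P_ij - pi_j P_ji|."""
    if sp.issparse(P):
        F = sp.diags(pi) @ P
        return float(abs(F - F.T).max()) if F.nnz else 0.0
    F = pi[:, None] * np.asarray(P)
    return float(np.max(np.abs(F - F.T)))


def build_state_graph(
    chain: ChainDefinition, instance, max_states: Optional[int] = 20000
) -> StateGraph:
    """Convenience: scan plus Metropolis finalization with the chain's weights."""
    graph = construct_state_graph(chain, instance, max_states=max_states)
    return finalize_transitions(graph, chain.weights)


@dataclass(frozen=True)
class ErgodicityReport:
    connected: bool
    aperiodic: bool
    reversible: bool
    balance_residual: float

    @property
    def ergodic(self) -> bool:
        return self.connected and self.aperiodic and self.reversible


def _nonloop_graph(graph: StateGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.num_states))
    g.add_edges_from((i, j) for i, j in graph.nonloop_arcs())
    return g


def check_ergodicity(graph: StateGraph) -> ErgodicityReport:
    """Preconditions of the fundamental theorem: connected, aperiodic,
    reversible.  Aperiodicity uses loop presence or non-bipartiteness of
    the non-loop arc graph (sufficient for loop-carrying chains, and far
    cheaper than a cycle-gcd computation)."""
    n = graph.num_states
    if n == 1:
        return ErgodicityReport(True, True, True, 0.0)
    arcs = list(graph.nonloop_arcs())
    if not arcs:
        return ErgodicityReport(False, False, True, 0.0)
    rows, cols = zip(*arcs)
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=True, connection="strong")
    connected = ncomp == 1
    has_loop = bool(np.any(graph.loop_probabilities() > 0))
    if has_loop:
        aperiodic = True
    else:
        aperiodic = connected and not nx.is_bipartite(_nonloop_graph(graph))
    residual = detailed_balance_residual(graph.P, graph.pi)
    return ErgodicityReport(connected, aperiodic, residual <= BALANCE_TOL, residual)


def reduce_loops(graph: StateGraph, keep_fraction: float = 0.99) -> StateGraph:
    """Strip ``keep_fraction`` of the minimal loop probability everywhere.

    With P_min = min_i P_ii, the composed map
    P' = (P - keep_fraction * P_min * I) / (1 - keep_fraction * P_min)
    subtracts the same amount from every loop and rescales so rows again
    sum to one.  Requires a uniform stationary distribution (the map
    preserves symmetry of P, hence pi); a non-uniform pi is refused.
    """
    if graph.pi is None:
        raise MixtimeError("finalize transitions before reducing loops")
    n = graph.num_states
    if np.max(np.abs(graph.pi - 1.0 / n)) > 1e-9:
        raise MixtimeError("loop reduction requires a uniform stationary distribution")
    if n == 1:
        return graph
    p_min = float(graph.loop_probabilities().min())
    cut = keep_fraction * p_min
    if cut == 0.0:
        return graph
    if sp.issparse(graph.P):
        P = (graph.P - cut * sp.identity(n, format="csr")) / (1.0 - cut)
    else:
        P = (graph.P - cut * np.eye(n)) / (1.0 - cut)
    out = replace(graph, P=P)
    _assert_finalized_invariants(out)
    return out


def reduce_loops_matrix(P, keep_fraction: float = 0.99):
    """Matrix-level form of :func:`reduce_loops` for symmetric P.

    P' = (P - keep_fraction * min_i P_ii * I) / (1 - keep_fraction * min_i P_ii).
    """
    n = P.shape[0]
    if n == 1:
        return P
    p_min = float(P.diagonal().min()) if sp.issparse(P) else float(np.diag(P).min())
    cut = keep_fraction * p_min
    if cut == 0.0:
        return P
    eye = sp.identity(n, format="csr") if sp.issparse(P) else np.eye(n)
    return (P - cut * eye) / (1.0 - cut)


def diameter(graph: StateGraph) -> int:
    """Longest unweighted shortest path over non-loop arcs."""
    if graph.num_states == 1:
        return 0
    g = _nonloop_graph(graph)
    if not nx.is_connected(g):
        raise NonErgodicError("state graph is disconnected: diameter is infinite")
    return nx.diameter(g)


def average_path_length(graph: StateGraph) -> float:
    """Mean shortest-path length over ordered pairs x != y."""
    if graph.num_states == 1:
        return 0.0
    g = _nonloop_graph(graph)
    if not nx.is_connected(g):
        raise NonErgodicError("state graph is disconnected")
    return nx.average_shortest_path_length(g)


def export_state_graph(graph: StateGraph, arcs_path, states_path) -> None:
    """TSV export: ``src<TAB>dst<TAB>P`` (0-based, 17 significant digits)
    plus a sidecar ``index<TAB>canonical-state-string`` file."""
    P = graph.P
    with open(arcs_path, "w") as fh:
        if sp.issparse(P):
            coo = P.tocoo()
            entries = sorted(zip(coo.row, coo.col, coo.data))
        else:
            entries = [
                (i, j, P[i, j])
                for i in range(graph.num_states)
                for j in range(graph.num_states)
                if P[i, j] != 0.0
            ]
        for i, j, p in entries:
            fh.write(f"{i}\t{j}\t{p:.17g}\n")
    with open(states_path, "w") as fh:
        for i, s in enumerate(graph.states):
            fh.write(f"{i}\t{s}\n")
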