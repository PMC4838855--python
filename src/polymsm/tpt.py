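"""Transition path theory: committors, reactive flux, pathway
decomposition, and the stepwise-vs-concerted mechanism fraction.

Given a Markov model and disjoint source (A) and sink (B) microstate
sets, the forward committor q+ is the probability of reaching B before A;
the gross reactive flux f_ij = pi_i q-_i T_ij q+_j measures the
probability current of A→B transition paths through each edge, and the
net flux f+_ij = max(0, f_ij - f_ji) satisfies Kirchhoff conservation at
every intermediate state. Iterative widest-path (bottleneck)
decomposition splits the net flux into individual pathways; classifying
each pathway by whether it visits the intermediate macrostates yields the
fraction of flux carried by the stepwise versus the concerted mechanism.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientCoverageError,
    InvalidSetsError,
    NoPathError,
)
from .msm import MarkovModel, stationary_distribution

__all__ = [
    "FluxNetwork",
    "committor",
    "reactive_flux",
    "decompose_pathways",
    "mechanism_fraction",
]


@dataclass
class FluxNetwork:
    source: np.ndarray
    sink: np.ndarray
    forward_committor: np.ndarray
    backward_committor: np.ndarray
    gross_flux: np.ndarray   # per lag time
    net_flux: np.ndarray
    total_flux: float
    lag_time: float = 1.0

    @property
    def n_states(self) -> int:
        return self.gross_flux.shape[0]


def _check_sets(n: int, A, B):
    A = np.asarray(sorted(set(int(a) for a in A)), dtype=int)
    B = np.asarray(sorted(set(int(b) for b in B)), dtype=int)
    if A.size == 0 or B.size == 0:
        raise InvalidSetsError("source and sink sets must be non-empty")
    if np.intersect1d(A, B).size:
        raise InvalidSetsError("source and sink sets overlap")
    if A.min() < 0 or A.max() >= n or B.min() < 0 or B.max() >= n:
        raise InvalidSetsError("state indices out of range")
    return A, B


def committor(T: np.ndarray, A, B) -> np.ndarray:
    """Forward committor q+: probability of hitting B before A.

    Solves the discrete boundary-value problem q_i = sum_j T_ij q_j for
    i outside A ∪ B, with q = 0 on A and q = 1 on B.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    A, B = _check_sets(n, A, B)
    q = np.zeros(n)
    q[B] = 1.0
    interior = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if interior.size:
        M = np.eye(interior.size) - T[np.ix_(interior, interior)]
        rhs = T[np.ix_(interior, B)].sum(axis=1)
        q[interior] = np.linalg.solve(M, rhs)
    return q


def backward_committor(T: np.ndarray, pi: np.ndarray, A, B) -> np.ndarray:
    """Backward committor q-: probability the chain came from A rather than B.

    Computed on the time-reversed chain T~_ij = pi_j T_ji / pi_i; for a
    reversible chain this equals 1 - q+.
    """
    T = np.asarray(T, dtype=float)
    pi = np.asarray(pi, dtype=float)
    Trev = (T.T * pi[None, :]) / pi[:, None]
    return committor(Trev, B, A)


def reactive_flux(model: MarkovModel, A, B) -> FluxNetwork:
    """Gross and net reactive flux of A→B transition paths.

    f_ij = pi_i q-_i T_ij q+_j (i != j), f+_ij = max(0, f_ij - f_ji);
    total flux = sum of net flux out of A. Fluxes carry units of
    probability per lag time.
    """
    T = model.transition_matrix
    n = model.n_states
    A, B = _check_sets(n, A, B)
    pi = model.stationary
    qp = committor(T, A, B)
    if model.estimator == "reversible":
        qm = 1.0 - qp
    else:
        qm = backward_committor(T, pi, A, B)
    f = (pi * qm)[:, None] * T * qp[None, :]
    np.fill_diagonal(f, 0.0)
    net = np.clip(f - f.T, 0.0, None)
    notA = np.setdiff1d(np.arange(n), A)
    total = float(net[np.ix_(A, notA)].sum())
    return FluxNetwork(
        source=A, sink=B, forward_committor=qp, backward_committor=qm,
        gross_flux=f, net_flux=net, total_flux=total, lag_time=model.lag_time,
    )


def _widest_path(cap: np.ndarray, A: np.ndarray, B: np.ndarray):
    """Maximum-bottleneck path from the A set to the B set.

    Ties between equal-bottleneck paths break toward the shorter path,
    then lexicographic state order. Two phases: a bottleneck-only Dijkstra
    for the optimal bottleneck value b*, then a shortest (BFS-level)
    lexicographically smallest path in the subgraph of edges with
    capacity >= b*. Returns (path, bottleneck) or None.
    """
    n = cap.shape[0]
    in_B = np.zeros(n, dtype=bool)
    in_B[B] = True
    # phase 1: widest-path Dijkstra (max-min label setting)
    heap = [(-np.inf, int(a)) for a in A]
    heapq.heapify(heap)
    settled = np.zeros(n, dtype=bool)
    bstar = None
    while heap:
        negb, u = heapq.heappop(heap)
        if settled[u]:
            continue
        settled[u] = True
        if in_B[u]:
            bstar = -negb
            break
        for v in np.flatnonzero(cap[u] > 0):
            if not settled[v]:
                heapq.heappush(heap, (max(negb, -cap[u, int(v)]), int(v)))
    if bstar is None or not np.isfinite(bstar) or bstar <= 0:
        return None
    # phase 2: shortest path using only edges with capacity >= b*,
    # lexicographically smallest among the shortest
    ok = cap >= bstar
    dist = np.full(n, -1)
    frontier = list(B)
    for b in B:
        dist[b] = 0
    d = 0
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(ok[:, u]):
                if dist[v] < 0:
                    dist[v] = d + 1
                    nxt.append(int(v))
        frontier = nxt
        d += 1
    starts = [a for a in A if dist[a] >= 0]
    if not starts:
        return None
    start = min(starts, key=lambda a: (dist[a], a))
    path = [int(start)]
    u = start
    while not in_B[u]:
        candidates = [int(v) for v in np.flatnonzero(ok[u]) if dist[v] == dist[u] - 1]
        u = min(candidates)
        path.append(u)
    return path, float(bstar)


def decompose_pathways(
    net: FluxNetwork,
    max_paths: int = 1000,
    residual_tol: float = 1e-12,
) -> list[dict]:
    """Iterative bottleneck decomposition of the net flux into pathways.

    Repeatedly finds the A→B path whose minimum-capacity edge is maximal,
    records it with its bottleneck flux, and subtracts that flux along the
    path, until ``max_paths`` paths are found or the residual flux drops
    below ``residual_tol`` of the total. Returns an ordered list of
    records (path, flux, fraction, cumulative_fraction).
    """
    if net.total_flux <= 0:
        raise NoPathError("total reactive flux is zero")
    cap = net.net_flux.copy()
    # edges into A or out of B cannot be part of a simple reactive path
    cap[:, net.source] = 0.0
    cap[net.sink, :] = 0.0
    out = []
    remaining = net.total_flux
    cum = 0.0
    for _ in range(max_paths):
        if remaining <= residual_tol * net.total_flux:
            break
        found = _widest_path(cap, net.source, net.sink)
        if found is None:
            break
        path, bottleneck = found
        if bottleneck <= 0:
            break
        idx = np.array(path)
        cap[idx[:-1], idx[1:]] -= bottleneck
        remaining -= bottleneck
        frac = bottleneck / net.total_flux
        cum += frac
        out.append({"path": path, "flux": bottleneck,
                    "fraction": frac, "cumulative_fraction": cum})
    if not out:
        raise NoPathError("no pathway connects the source to the sink")
    return out


def mechanism_fraction(
    pathways: list[dict],
    intermediate_states,
    min_coverage: float = 0.999,
) -> dict[str, float]:
    """Flux fraction carried by the stepwise vs the concerted mechanism.

    A pathway is *stepwise* if it visits any designated intermediate
    microstate (microstates of the intermediate macrostates, e.g. S2/S3),
    else *concerted*. Requires the decomposition to cover at least
    ``min_coverage`` of the total flux. Fractions are of total flux.
    """
    inter = set(int(s) for s in intermediate_states)
    coverage = pathways[-1]["cumulative_fraction"] if pathways else 0.0
    if coverage < min_coverage:
        raise InsufficientCoverageError(
            f"decomposition covers {coverage:.5f} < {min_coverage} of total flux"
        )
    stepwise = sum(p["fraction"] for p in pathways
                   if inter.intersection(p["path"][1:-1]) or inter.intersection(p["path"]))
    concerted = sum(p["fraction"] for p in pathways
                    if not (inter.intersection(p["path"][1:-1]) or inter.intersection(p["path"])))
    return {"stepwise": stepwise, "concerted": concerted, "coverage": coverage}
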