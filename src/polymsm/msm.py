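"""Microstate Markov model estimation and validation.

Pipeline: count lagged transitions over a pool of discrete trajectories,
trim to the largest strongly connected (ergodic) set, estimate a
row-stochastic transition matrix — by default the symmetrized-count
reversible estimator, which guarantees detailed balance and a real
spectrum — then validate with implied-timescale plateaus and the
residence-probability (Chapman–Kolmogorov-style) self-consistency test.

Times: a model estimated at lag L frames with frame interval dt carries a
physical lag time tau = L * dt; implied timescales are
t_k = -tau / ln lambda_{k+1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import NonErgodicError, NoTransitionsError

__all__ = [
    "CountMatrix",
    "MarkovModel",
    "count_transitions",
    "trim_to_ergodic",
    "estimate_transition_matrix",
    "stationary_distribution",
    "implied_timescales",
    "residence_probability_test",
]


@dataclass
class CountMatrix:
    counts: np.ndarray
    lag: int
    frame_interval: float = 1.0
    counting_mode: str = "sliding"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass
class MarkovModel:
    """Row-stochastic transition matrix with spectral decomposition.

    ``lag_time`` is in physical units (lag frames x frame interval).
    Eigen-triples are sorted by descending eigenvalue modulus; for the
    reversible estimator the spectrum is real and eigenvectors satisfy the
    pi-weighted orthogonality used by PCCA+.
    """

    transition_matrix: np.ndarray
    lag_time: float
    stationary: np.ndarray
    eigenvalues: np.ndarray
    left_eigenvectors: np.ndarray   # rows-compatible: columns are left eigvecs
    right_eigenvectors: np.ndarray  # columns are right eigvecs
    estimator: str = "reversible"
    frame_interval: float = 1.0
    lag: int = 1
    state_map: np.ndarray | None = None  # original state index of each model state

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales -tau/ln(lambda) for the non-unit eigenvalues.

        Complex or non-positive eigenvalues yield NaN (undefined), never a
        silently dropped entry.
        """
        lam = self.eigenvalues[1:None if n is None else n + 1]
        out = np.full(lam.shape, np.nan)
        ok = np.isreal(lam) & (np.real(lam) > 0) & (np.real(lam) < 1)
        out[ok] = -self.lag_time / np.log(np.real(lam[ok]))
        out[np.isreal(lam) & (np.real(lam) >= 1)] = np.inf
        return out


def count_transitions(trajs, lag: int, mode: str = "sliding", n_states: int | None = None,
                      frame_interval: float = 1.0) -> CountMatrix:
    """Pool lagged transition counts over trajectories.

    Sliding mode counts every pair (s_t, s_{t+lag}); strided counts only
    t = 0, lag, 2 lag, ... Trajectories shorter than lag+1 contribute
    nothing; if none contributes, a no-transitions error is raised.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown counting mode {mode!r}")
    trajs = [np.asarray(t, dtype=np.int64) for t in trajs]
    if n_states is None:
        n_states = max((int(t.max()) + 1 for t in trajs if t.size), default=0)
    counts = np.zeros((n_states, n_states))
    total = 0
    for t in trajs:
        if t.size <= lag:
            continue
        if mode == "sliding":
            i, j = t[:-lag], t[lag:]
        else:
            i = t[:-lag:lag]
            j = t[lag::lag]
        np.add.at(counts, (i, j), 1.0)
        total += len(i)
    if total == 0:
        raise NoTransitionsError(f"no trajectory longer than lag {lag}")
    return CountMatrix(counts, lag=lag, frame_interval=frame_interval, counting_mode=mode)


def trim_to_ergodic(cm: CountMatrix):
    """Restrict to the largest strongly connected component of the count graph.

    Component ties break by larger total counts, then by lowest member
    state index. Returns the trimmed count matrix and the kept-state map
    (array of original indices, position = new index).
    """
    if cm.counts.size == 0 or cm.counts.sum() == 0:
        raise NoTransitionsError("count matrix is empty")
    n = cm.n_states
    graph = csr_matrix(cm.counts > 0)
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    best = None
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        size = members.size
        tot = cm.counts[np.ix_(members, members)].sum()
        key = (size, tot, -members[0])
        if best is None or key > best[0]:
            best = (key, members)
    kept = best[1]
    trimmed = CountMatrix(
        cm.counts[np.ix_(kept, kept)], lag=cm.lag,
        frame_interval=cm.frame_interval, counting_mode=cm.counting_mode,
    )
    return trimmed, kept


def _spectral(T: np.ndarray, pi: np.ndarray, reversible: bool):
    if reversible:
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
        S = (S + S.T) / 2.0
        w, phi = np.linalg.eigh(S)
        order = np.argsort(-w)
        w = w[order]
        phi = phi[:, order]
        right = phi / sqrt_pi[:, None]
        left = phi * sqrt_pi[:, None]
        # normalize the stationary pair: right eigvec 1 = ones, left = pi
        right[:, 0] = right[:, 0] / right[0, 0]
        left[:, 0] = left[:, 0] * np.sign(left[:, 0].sum())
        return w, left, right
    w, vr = np.linalg.eig(T)
    wl, vl = np.linalg.eig(T.T)
    order = np.argsort(-np.abs(w))
    w = w[order]
    vr = vr[:, order]
    vl = vl[:, np.argsort(-np.abs(wl))]
    return w, vl, vr


def estimate_transition_matrix(cm: CountMatrix, reversible: bool = True) -> MarkovModel:
    """Estimate a Markov model from a (trimmed, ergodic) count matrix.

    reversible (default): symmetrize counts c' = (c + c^T)/2 then row
    normalize — detailed balance holds by construction and the stationary
    distribution equals the normalized symmetrized row sums. Non-reversible:
    plain row normalization, stationary from the leading left eigenvector.
    """
    C = cm.counts
    if reversible:
        C = (C + C.T) / 2.0
    rows = C.sum(axis=1)
    if np.any(rows == 0):
        raise NonErgodicError("zero count row; trim to the ergodic set first")
    T = C / rows[:, None]
    if reversible:
        pi = rows / rows.sum()
    else:
        pi = stationary_distribution(T)
    w, left, right = _spectral(T, pi, reversible)
    return MarkovModel(
        transition_matrix=T,
        lag_time=cm.lag * cm.frame_interval,
        stationary=pi,
        eigenvalues=w,
        left_eigenvectors=left,
        right_eigenvectors=right,
        estimator="reversible" if reversible else "nonreversible",
        frame_interval=cm.frame_interval,
        lag=cm.lag,
    )


def model_from_matrix(T: np.ndarray, lag_time: float = 1.0,
                      reversible: bool | None = None) -> MarkovModel:
    """Wrap a known transition matrix as a MarkovModel (exact reference).

    ``reversible`` is detected from detailed balance when not given; used
    for ground-truth chains whose kinetic quantities are computed exactly.
    """
    T = np.asarray(T, dtype=float)
    pi = stationary_distribution(T)
    if reversible is None:
        flux = pi[:, None] * T
        reversible = bool(np.max(np.abs(flux - flux.T)) < 1e-10)
    w, left, right = _spectral(T, pi, reversible)
    return MarkovModel(
        transition_matrix=T, lag_time=lag_time, stationary=pi,
        eigenvalues=w, left_eigenvectors=left, right_eigenvectors=right,
        estimator="reversible" if reversible else "nonreversible",
        frame_interval=lag_time, lag=1,
    )


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Unique stationary distribution of an irreducible row-stochastic matrix."""
    T = np.asarray(T, dtype=float)
    n_comp, _ = connected_components(csr_matrix(T > 0), directed=True, connection="strong")
    if n_comp != 1:
        raise NonErgodicError("transition matrix is reducible")
    w, v = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.abs(np.real(v[:, i]))
    return pi / pi.sum()


def implied_timescales(
    trajs,
    lags,
    n_timescales: int = 3,
    frame_interval: float = 1.0,
    reversible: bool = True,
) -> pd.DataFrame:
    """Implied timescales t_k(tau) = -tau/ln(lambda_{k+1}) per candidate lag.

    Returns a tidy table (lag, k, eigenvalue, timescale); undefined
    timescales (complex/negative eigenvalues, or a lag at which the chain
    disconnects) appear as NaN rows — they diagnose non-Markovian or
    under-sampled lags rather than being dropped.
    """
    rows = []
    for lag in lags:
        try:
            cm = count_transitions(trajs, lag=lag, frame_interval=frame_interval)
            trimmed, _ = trim_to_ergodic(cm)
            model = estimate_transition_matrix(trimmed, reversible=reversible)
        except (NoTransitionsError, NonErgodicError) as exc:
            for k in range(1, n_timescales + 1):
                rows.append({"lag": lag, "k": k, "eigenvalue": np.nan,
                             "timescale": np.nan, "note": str(exc)})
            continue
        ts = model.timescales(n_timescales)
        lam = model.eigenvalues[1:n_timescales + 1]
        for k in range(1, n_timescales + 1):
            ev = lam[k - 1] if k - 1 < len(lam) else np.nan
            t = ts[k - 1] if k - 1 < len(ts) else np.nan
            rows.append({"lag": lag, "k": k, "eigenvalue": np.real_if_close(ev),
                         "timescale": t, "note": ""})
    return pd.DataFrame(rows)


def residence_probability_test(
    model: MarkovModel,
    trajs,
    multiples,
    states,
) -> pd.DataFrame:
    """Compare model-predicted and empirical residence probabilities.

    predicted(i, k) = [T^k]_ii ; empirical(i, k) = fraction of trajectory
    positions t with s_t = i for which s_{t + k*lag} = i. States never
    visited at a horizon are excluded with a warning entry. Trajectories
    must be expressed in model state indices.
    """
    trajs = [np.asarray(t, dtype=np.int64) for t in trajs]
    rows = []
    Tk = {0: np.eye(model.n_states)}
    for k in sorted(set(int(m) for m in multiples)):
        Tk[k] = np.linalg.matrix_power(model.transition_matrix, k)
        horizon = k * model.lag
        for i in states:
            hits = 0
            starts = 0
            for t in trajs:
                if t.size <= horizon:
                    continue
                at_i = t[:-horizon] == i if horizon else t == i
                starts += int(at_i.sum())
                hits += int((t[horizon:][at_i] == i).sum())
            if starts == 0:
                rows.append({"state": i, "k": k, "horizon": horizon * model.frame_interval,
                             "predicted": Tk[k][i, i], "empirical": np.nan,
                             "n_starts": 0, "note": "state not visited at this horizon"})
                continue
            rows.append({"state": i, "k": k, "horizon": horizon * model.frame_interval,
                         "predicted": Tk[k][i, i], "empirical": hits / starts,
                         "n_starts": starts, "note": ""})
    df = pd.DataFrame(rows)
    df["mismatch"] = np.abs(df["predicted"] - df["empirical"])
    return df
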