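"""Mean first passage times, model-generated long trajectories, and
trajectory-level bootstrap uncertainties.

MFPTs solve the linear system m_i = tau + sum_j T_ij m_j (m = 0 on the
target set); macrostate MFPTs aggregate microstate MFPTs over the source
macrostate with stationary weights renormalized within the source. The
bootstrap resamples whole trajectories with replacement (original count
per replicate), re-estimates the microstate model per replicate, and
reports mean ± SD of macrostate populations and MFPTs over replicates;
the lumping is frozen from the full-data model so replicate labels cannot
switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InvalidDurationError,
    InvalidParameterError,
    NonErgodicError,
    UnreachableTargetError,
)
from .macrostates import Lumping, macro_populations, pcca_plus
from .msm import (
    CountMatrix,
    MarkovModel,
    count_transitions,
    estimate_transition_matrix,
    trim_to_ergodic,
)

__all__ = [
    "KineticsReport",
    "mfpt_to_set",
    "mfpt_macro",
    "mfpt_macro_matrix",
    "sample_model_trajectory",
    "bootstrap_kinetics",
    "empirical_mfpt",
]


def mfpt_to_set(model: MarkovModel, targets) -> np.ndarray:
    """MFPT from every microstate to a target set, in physical time units.

    m_i = 0 for i in targets; otherwise m_i = tau + sum_j T_ij m_j, solved
    as one linear system. Raises if the target set is unreachable from any
    state (singular system).
    """
    targets = np.asarray(sorted(set(int(t) for t in targets)), dtype=int)
    if targets.size == 0:
        raise InvalidParameterError("target set is empty")
    n = model.n_states
    T = model.transition_matrix
    tau = model.lag_time
    rest = np.setdiff1d(np.arange(n), targets)
    m = np.zeros(n)
    if rest.size:
        A = np.eye(rest.size) - T[np.ix_(rest, rest)]
        try:
            sol = np.linalg.solve(A, np.full(rest.size, tau))
        except np.linalg.LinAlgError:
            raise UnreachableTargetError(rest.tolist()) from None
        if not np.all(np.isfinite(sol)) or np.any(sol < -1e-9 * tau):
            raise UnreachableTargetError(rest[~np.isfinite(sol) | (sol < 0)].tolist())
        m[rest] = sol
    return m


def mfpt_macro(
    model: MarkovModel,
    lumping: Lumping,
    source: int,
    target: int,
    weights: str = "stationary",
) -> float:
    """Macrostate MFPT: weighted microstate MFPT over the source macrostate.

    Weights are the stationary probabilities renormalized within the source
    (``weights="uniform"`` gives the unweighted sensitivity variant).
    """
    if source == target:
        raise InvalidParameterError("source and target macrostates must differ")
    m = mfpt_to_set(model, lumping.members(target))
    src = lumping.members(source)
    if weights == "uniform":
        w = np.full(src.size, 1.0 / src.size)
    else:
        pi = model.stationary[src]
        w = pi / pi.sum()
    return float(w @ m[src])


def mfpt_macro_matrix(model: MarkovModel, lumping: Lumping, weights: str = "stationary") -> np.ndarray:
    """All source x target macrostate MFPTs (diagonal 0)."""
    M = np.zeros((lumping.n_macro, lumping.n_macro))
    for a in range(lumping.n_macro):
        for b in range(lumping.n_macro):
            if a != b:
                M[a, b] = mfpt_macro(model, lumping, a, b, weights=weights)
    return M


def sample_model_trajectory(
    model: MarkovModel,
    duration: float,
    start=0,
    seed: int = 0,
) -> np.ndarray:
    """Generate a long synthetic state trajectory from the model.

    ``duration`` is physical time; the trajectory has round(duration/tau)
    steps at the model's lag time, used to recompute observables (dwell
    times, residence statistics) on timescales far beyond the input data.
    ``start`` may be a state index, a probability vector, or "stationary".
    """
    if duration < model.lag_time:
        raise InvalidDurationError("duration must be at least one lag time")
    n_steps = int(round(duration / model.lag_time))
    rng = np.random.default_rng(seed)
    if isinstance(start, str) and start == "stationary":
        s = int(rng.choice(model.n_states, p=model.stationary))
    elif np.ndim(start) == 0:
        s = int(start)
        if not (0 <= s < model.n_states):
            raise InvalidParameterError(f"start state {s} out of range")
    else:
        p = np.asarray(start, dtype=float)
        s = int(rng.choice(model.n_states, p=p / p.sum()))
    cum = np.cumsum(model.transition_matrix, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_steps)
    out = np.empty(n_steps + 1, dtype=np.int64)
    out[0] = s
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        out[t + 1] = s
    return out


def empirical_mfpt(traj: np.ndarray, source, targets, frame_interval: float = 1.0) -> float:
    """MFPT estimated from a trajectory: mean time from source visits to the
    next entry into the target set (occupancy-weighted, matching the
    stationary-weighted linear-solve aggregation)."""
    traj = np.asarray(traj, dtype=np.int64)
    targets = set(int(t) for t in targets)
    source = set(int(s) for s in np.atleast_1d(source))
    in_b = np.isin(traj, list(targets))
    # next_hit[t] = first index >= t with traj in targets
    n = traj.size
    next_hit = np.full(n, n, dtype=np.int64)
    nxt = n
    for t in range(n - 1, -1, -1):
        if in_b[t]:
            nxt = t
        next_hit[t] = nxt
    at_src = np.isin(traj, list(source)) & (next_hit < n)
    if not np.any(at_src):
        raise UnreachableTargetError(sorted(source))
    waits = (next_hit - np.arange(n))[at_src]
    return float(waits.mean() * frame_interval)


@dataclass
class KineticsReport:
    """Bootstrap summary of macrostate populations and MFPTs.

    Populations are percentages; MFPT units follow the model's time units.
    """

    macro_labels: list[str]
    population_mean: np.ndarray
    population_sd: np.ndarray
    mfpt_mean: np.ndarray
    mfpt_sd: np.ndarray
    n_bootstrap: int
    n_failed: int
    lag_time: float
    time_unit: str = "ns"

    def population_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "macrostate": self.macro_labels,
            "population_pct": self.population_mean,
            "sd_pct": self.population_sd,
        })

    def mfpt_table(self) -> pd.DataFrame:
        rows = []
        for a, la in enumerate(self.macro_labels):
            for b, lb in enumerate(self.macro_labels):
                if a != b:
                    rows.append({"from": la, "to": lb,
                                 "mfpt": self.mfpt_mean[a, b],
                                 "sd": self.mfpt_sd[a, b]})
        return pd.DataFrame(rows)

    def format_lines(self, mfpt_unit: str | None = None, mfpt_scale: float = 1.0) -> list[str]:
        """Human-readable lines: populations as '10.5±1.5%', MFPTs as '95.9±42.3 μs'."""
        unit = mfpt_unit or self.time_unit
        lines = ["Equilibrium populations:"]
        for lab, mu, sd in zip(self.macro_labels, self.population_mean, self.population_sd):
            lines.append(f"  {lab}: {mu:.1f}±{sd:.1f}%")
        lines.append("Mean first passage times:")
        for a, la in enumerate(self.macro_labels):
            for b, lb in enumerate(self.macro_labels):
                if a != b:
                    mu = self.mfpt_mean[a, b] * mfpt_scale
                    sd = self.mfpt_sd[a, b] * mfpt_scale
                    lines.append(f"  {la}→{lb}: {mu:.1f}±{sd:.1f} {unit}")
        return lines


def _replicate_kinetics(cm: CountMatrix, macro_of_state: np.ndarray, n_macro: int,
                        reversible: bool, weights: str):
    trimmed, kept = trim_to_ergodic(cm)
    model = estimate_transition_matrix(trimmed, reversible=reversible)
    macro_kept = macro_of_state[kept]
    if np.any(macro_kept < 0) or len(set(macro_kept.tolist())) < n_macro:
        raise NonErgodicError("replicate lost a macrostate")
    chi = np.zeros((kept.size, n_macro))
    chi[np.arange(kept.size), macro_kept] = 1.0
    lump = Lumping(membership=chi, crisp_assignment=macro_kept.astype(np.int64),
                   n_macro=n_macro)
    pops = macro_populations(model.stationary, lump)
    mfpts = mfpt_macro_matrix(model, lump, weights=weights)
    return pops, mfpts


def bootstrap_kinetics(
    trajs,
    B: int = 100,
    seed: int = 0,
    lag: int = 1,
    frame_interval: float = 1.0,
    n_macro: int = 4,
    reversible: bool = True,
    weights: str = "stationary",
    lumping: Lumping | None = None,
    macro_labels: list[str] | None = None,
) -> KineticsReport:
    """Trajectory-level bootstrap of macrostate populations and MFPTs.

    Each of the B replicates draws ``len(trajs)`` trajectories with
    replacement, re-counts and re-estimates the microstate model, applies
    the lumping frozen from the full-data model (or the one supplied), and
    records macrostate populations and MFPTs. Replicates that lose ergodic
    connection to any macrostate are excluded and counted as failed.
    Deterministic under ``seed``.
    """
    if B < 2:
        raise InvalidParameterError("B must be >= 2")
    trajs = [np.asarray(t, dtype=np.int64) for t in trajs]
    if len(trajs) < 2:
        raise InvalidParameterError("need at least 2 trajectories to bootstrap")
    n_states = max(int(t.max()) + 1 for t in trajs)
    per_traj = [count_transitions([t], lag=lag, n_states=n_states,
                                  frame_interval=frame_interval).counts for t in trajs]
    full = CountMatrix(np.sum(per_traj, axis=0), lag=lag, frame_interval=frame_interval)
    trimmed, kept = trim_to_ergodic(full)
    full_model = estimate_transition_matrix(trimmed, reversible=reversible)
    if lumping is None:
        lumping = pcca_plus(full_model, n_macro)
    macro_of_state = np.full(n_states, -1, dtype=int)
    macro_of_state[kept] = lumping.crisp_assignment

    rng = np.random.default_rng(seed)
    pops, mfpts = [], []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(len(trajs), size=len(trajs))
        counts = np.sum([per_traj[i] for i in idx], axis=0)
        cm = CountMatrix(counts, lag=lag, frame_interval=frame_interval)
        try:
            p, m = _replicate_kinetics(cm, macro_of_state, lumping.n_macro,
                                       reversible, weights)
        except (NonErgodicError, UnreachableTargetError):
            n_failed += 1
            continue
        pops.append(p)
        mfpts.append(m)
    if len(pops) < 2:
        raise NonErgodicError(f"only {len(pops)} bootstrap replicates succeeded")
    pops = np.array(pops) * 100.0
    mfpts = np.array(mfpts)
    return KineticsReport(
        macro_labels=macro_labels or lumping.macro_labels,
        population_mean=pops.mean(axis=0),
        population_sd=pops.std(axis=0, ddof=1),
        mfpt_mean=mfpts.mean(axis=0),
        mfpt_sd=mfpts.std(axis=0, ddof=1),
        n_bootstrap=B,
        n_failed=n_failed,
        lag_time=lag * frame_interval,
    )
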