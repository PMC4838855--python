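"""PCCA+ lumping of microstates into metastable macrostates.

Robust Perron Cluster Cluster Analysis (inner-simplex variant): the rows
of the top-m pi-orthonormal right eigenvectors of a reversible transition
matrix lie, for a metastable chain, near the vertices of an
(m-1)-simplex; each vertex corresponds to one metastable set. The
algorithm locates m extreme rows, maps all rows onto barycentric
membership weights via the inverse vertex matrix, and clips/renormalizes
into [0, 1]. Crisp assignments take the row argmax (ties to the lower
macrostate index).

All downstream kinetics are computed at the microstate level and only
reported per macrostate; the lumped model is used for labeling and
reporting, not for quantitative propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateSpectrumError,
    EmptyMacrostateError,
    InvalidLumpingError,
)
from .msm import MarkovModel

__all__ = [
    "Lumping",
    "pcca_plus",
    "macro_populations",
    "representative_conformations",
    "sort_macrostates",
]


@dataclass
class Lumping:
    """Microstate → macrostate membership weights and crisp assignment."""

    membership: np.ndarray          # (n_micro, n_macro), rows sum to 1
    crisp_assignment: np.ndarray    # (n_micro,), argmax of each row
    n_macro: int
    macro_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        chi = np.asarray(self.membership, dtype=float)
        if np.any(chi < -1e-12) or np.max(np.abs(chi.sum(axis=1) - 1.0)) > 1e-8:
            raise InvalidLumpingError("membership rows must be a partition of unity")
        if not np.array_equal(self.crisp_assignment, np.argmax(chi, axis=1)):
            raise InvalidLumpingError("crisp assignment must be the row argmax")
        for m in range(self.n_macro):
            if not np.any(self.crisp_assignment == m):
                raise InvalidLumpingError(f"macrostate {m} is empty")
        if not self.macro_labels:
            self.macro_labels = [f"S{m + 1}" for m in range(self.n_macro)]

    @property
    def n_micro(self) -> int:
        return self.membership.shape[0]

    def members(self, macro: int) -> np.ndarray:
        return np.flatnonzero(self.crisp_assignment == macro)


def _inner_simplex_vertices(X: np.ndarray) -> list[int]:
    """Indices of m extreme rows of X spanning the membership simplex."""
    n, m = X.shape
    ortho = X.copy()
    idx = [int(np.argmax(np.linalg.norm(ortho, axis=1)))]
    ortho = ortho - ortho[idx[0]]
    for _ in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        nxt = int(np.argmax(norms))
        idx.append(nxt)
        v = ortho[nxt] / norms[nxt]
        ortho = ortho - np.outer(ortho @ v, v)
    return idx


def pcca_plus(model: MarkovModel, n_macro: int, vertex_pi_floor: float | None = None) -> Lumping:
    """Lump a reversible Markov model into ``n_macro`` metastable sets.

    Simplex vertices are chosen only among microstates whose stationary
    weight is at least ``vertex_pi_floor`` (default: a tenth of the
    uniform weight 1/n): sparsely sampled outlier microstates otherwise
    capture vertices and produce near-empty macrostates. All microstates
    still receive membership weights through the simplex transform.
    """
    n = model.n_states
    if not (2 <= n_macro <= n):
        raise InvalidLumpingError(f"n_macro={n_macro} outside [2, {n}]")
    if model.estimator != "reversible":
        raise InvalidLumpingError("PCCA+ requires a reversible model (real spectrum)")
    lam = np.real(model.eigenvalues)
    if n_macro < n and abs(lam[n_macro - 1] - lam[n_macro]) < 1e-10:
        raise DegenerateSpectrumError(
            f"eigenvalues {n_macro} and {n_macro + 1} are degenerate "
            f"({lam[n_macro - 1]:.12f}); choose a different n_macro"
        )
    X = np.real(model.right_eigenvectors[:, :n_macro]).copy()
    X[:, 0] = 1.0  # the stationary eigenvector is constant; pin it exactly
    if vertex_pi_floor is None:
        vertex_pi_floor = 0.1 / n
    candidates = np.flatnonzero(model.stationary >= vertex_pi_floor)
    if candidates.size < n_macro:
        candidates = np.arange(n)
    verts = candidates[_inner_simplex_vertices(X[candidates])]
    A = np.linalg.inv(X[verts])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1).astype(np.int64)
    # re-index macrostates so they appear in order of their first microstate
    # (stable under eigenvector sign flips)
    order = {}
    for m in crisp:
        if m not in order:
            order[m] = len(order)
    if len(order) < n_macro:
        raise InvalidLumpingError("PCCA+ produced an empty macrostate")
    perm = np.empty(n_macro, dtype=int)
    for old, new in order.items():
        perm[old] = new
    chi = chi[:, np.argsort(perm)]
    crisp = perm[crisp]
    return Lumping(membership=chi, crisp_assignment=crisp, n_macro=n_macro)


def macro_populations(pi: np.ndarray, lumping: Lumping) -> np.ndarray:
    """Equilibrium macrostate populations: crisp sums of microstate pi."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape[0] != lumping.n_micro:
        raise InvalidLumpingError("stationary vector length does not match lumping")
    pops = np.array([pi[lumping.members(m)].sum() for m in range(lumping.n_macro)])
    if np.any([lumping.members(m).size == 0 for m in range(lumping.n_macro)]):
        raise InvalidLumpingError("empty macrostate")
    return pops


def sort_macrostates(lumping: Lumping, order_values: np.ndarray) -> Lumping:
    """Relabel macrostates S1..Sn by ascending mean of a per-microstate value.

    ``order_values`` is typically the mean transition index or landscape
    pathway coordinate of each microstate's frames, so that labels follow
    the pathway order (S1 = pre-translocation-like end).
    """
    order_values = np.asarray(order_values, dtype=float)
    means = np.array([order_values[lumping.members(m)].mean() for m in range(lumping.n_macro)])
    rank = np.argsort(np.argsort(means))
    chi = lumping.membership[:, np.argsort(rank)]
    crisp = rank[lumping.crisp_assignment]
    return Lumping(membership=chi, crisp_assignment=crisp, n_macro=lumping.n_macro)


def representative_conformations(
    assignments: np.ndarray,
    lumping: Lumping,
    ensemble,
    per_macro: int = 1,
    max_reference_frames: int = 512,
) -> list[list[int]]:
    """Representative frame indices per macrostate.

    For each macrostate, frames of its most populated microstate are ranked
    by mean Euclidean distance (over reaction coordinates if present, else
    flattened coordinates) to the other frames of that microstate; the
    ``per_macro`` lowest-mean frames are returned (ties to the lower frame
    index). For large microstates the reference set is an evenly strided
    subsample of at most ``max_reference_frames`` frames.
    """
    assignments = np.asarray(assignments, dtype=np.int64)
    if ensemble.reaction_coords is not None:
        feats = np.asarray(ensemble.reaction_coords, dtype=float)
    else:
        feats = ensemble.coordinates.reshape(ensemble.n_frames, -1)
    out = []
    for m in range(lumping.n_macro):
        micro_members = lumping.members(m)
        frame_counts = [(np.sum(assignments == mi), -mi) for mi in micro_members]
        best_micro = micro_members[int(np.argmax([c for c, _ in frame_counts]))]
        frames = np.flatnonzero(assignments == best_micro)
        if frames.size == 0:
            raise EmptyMacrostateError(f"macrostate {m} has no frames")
        ref = frames
        if ref.size > max_reference_frames:
            ref = ref[:: int(np.ceil(ref.size / max_reference_frames))]
        d = np.linalg.norm(feats[frames][:, None, :] - feats[ref][None, :, :], axis=2)
        mean_d = d.mean(axis=1)
        order = np.lexsort((frames, mean_d))
        out.append([int(frames[i]) for i in order[:per_macro]])
    return out
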