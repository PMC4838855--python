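"""Geometric observables on conformational ensembles.

This module holds the in-memory trajectory container
(:class:`ConformationEnsemble`) and the observables computed on it:
Kabsch-superposed RMSD, per-particle RMSF, the dimensionless transition
index locating a conformation between a pre-translocation and a frayed
reference, destination classification of transition-state-seeded runs,
dynamic cross-correlation maps (DCCM) and distance-to-reference profiles.

Conventions
-----------
* Coordinates are (n_frames, n_particles, 3) arrays in nm; times in ns.
* Centers of mass use unit masses — the pseudo-particles produced by the
  synthetic generators carry no physical masses.
* Selection groups are named integer index sets stored on the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    AlignmentDegenerateError,
    DegenerateReferenceError,
    EmptyInputError,
    InsufficientFramesError,
    UnknownSelectionError,
    ZeroVarianceError,
)

__all__ = [
    "ConformationEnsemble",
    "TransitionIndexSpec",
    "kabsch_rmsd",
    "rmsf",
    "transition_index",
    "classify_ts_ensemble",
    "cross_correlation_map",
    "distance_to_reference",
]


@dataclass
class ConformationEnsemble:
    """Ordered coordinate frames of labeled pseudo-particles.

    Parameters
    ----------
    coordinates
        Array of shape (n_frames, n_particles, 3), nm.
    labels
        One unique name per particle column.
    frame_interval
        Time between saved frames, ns.
    groups
        Named selections (particle index arrays). Defaults to one singleton
        group per label.
    reaction_coords
        Optional low-dimensional coordinates per frame (n_frames, d), e.g.
        the underlying landscape position of a synthetic trajectory. Used by
        Euclidean-metric clustering and for ordering macrostates.
    """

    coordinates: np.ndarray
    labels: list[str]
    frame_interval: float = 1.0
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    reaction_coords: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_particles, 3)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates contain non-finite values")
        if len(self.labels) != self.coordinates.shape[1]:
            raise ValueError("one label per particle column required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not self.groups:
            self.groups = {lab: np.array([i]) for i, lab in enumerate(self.labels)}
        for name, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise ValueError(f"selection group {name!r} is empty")
            if idx.min() < 0 or idx.max() >= self.n_particles:
                raise ValueError(f"selection group {name!r} out of bounds")
            self.groups[name] = idx
        if self.reaction_coords is not None:
            self.reaction_coords = np.asarray(self.reaction_coords, dtype=float)
            if self.reaction_coords.shape[0] != self.n_frames:
                raise ValueError("reaction_coords must have one row per frame")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]

    def group_indices(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise UnknownSelectionError(name) from None

    def com(self, group: str) -> np.ndarray:
        """Unit-mass center of mass of a named group, per frame: (n_frames, 3)."""
        idx = self.group_indices(group)
        return self.coordinates[:, idx, :].mean(axis=1)

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]


@dataclass(frozen=True)
class TransitionIndexSpec:
    """References defining the pre→frayed transition index.

    ``r_pre`` and ``r_frayed`` are the probe-group centers of mass in the
    pre-translocation and frayed reference conformations; ``probe_group``
    names the group (by default the DNA transition-nucleotide analogue)
    whose center of mass is projected.
    """

    r_pre: np.ndarray
    r_frayed: np.ndarray
    probe_group: str = "DNA_TN"

    def __post_init__(self):
        object.__setattr__(self, "r_pre", np.asarray(self.r_pre, dtype=float))
        object.__setattr__(self, "r_frayed", np.asarray(self.r_frayed, dtype=float))
        if np.allclose(self.r_pre, self.r_frayed):
            raise DegenerateReferenceError("r_pre and r_frayed coincide")


def _centered(frame: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = np.asarray(frame, dtype=float)[idx]
    return sub - sub.mean(axis=0)


def kabsch_rmsd(
    ref: np.ndarray,
    mob: np.ndarray,
    group: np.ndarray | None = None,
    fit: bool = True,
) -> float:
    """RMSD between two frames over a particle selection.

    With ``fit=True`` the mobile frame is first superposed onto the
    reference by the optimal proper rotation/translation (Kabsch, via
    least-squares rotation fitting); with ``fit=False`` the raw deviation
    after centroid removal of neither frame is returned.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    if group is None:
        group = np.arange(ref.shape[0])
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        raise EmptyInputError("selection group is empty")
    a = ref[group]
    b = mob[group]
    if not fit:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    # rank < 2 means all points collinear (or coincident): rotation undefined
    if group.size < 3 or np.linalg.matrix_rank(ac, tol=1e-10) < 2:
        raise AlignmentDegenerateError("fit group is degenerate (collinear or coincident)")
    rot, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(group.size))


def superpose(frame: np.ndarray, onto: np.ndarray, fit_group: np.ndarray) -> np.ndarray:
    """Return ``frame`` rigidly superposed onto ``onto`` over ``fit_group``."""
    a = np.asarray(onto, dtype=float)[fit_group]
    b = np.asarray(frame, dtype=float)[fit_group]
    mu_a = a.mean(axis=0)
    mu_b = b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a - mu_a, b - mu_b)
    return rot.apply(np.asarray(frame, dtype=float) - mu_b) + mu_a


def rmsf(
    ensemble: ConformationEnsemble,
    group: str | np.ndarray | None = None,
    fit_group: str | np.ndarray | None = None,
    align: bool = True,
) -> np.ndarray:
    """Per-particle root-mean-square fluctuation about the mean structure.

    Frames are first superposed (over ``fit_group``, default: the whole
    particle set) onto the ensemble mean; the mean is then recomputed once
    and fluctuations are taken about it. ``align=False`` skips superposition
    for data already in a common frame (e.g. synthetic displacements).
    """
    if ensemble.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least two frames")
    idx = _resolve_group(ensemble, group)
    coords = ensemble.coordinates
    if align:
        fit_idx = _resolve_group(ensemble, fit_group)
        mean = coords.mean(axis=0)
        coords = np.array([superpose(f, mean, fit_idx) for f in coords])
        mean = coords.mean(axis=0)
    else:
        mean = coords.mean(axis=0)
    dev = coords[:, idx, :] - mean[idx]
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def _resolve_group(ensemble: ConformationEnsemble, group) -> np.ndarray:
    if group is None:
        return np.arange(ensemble.n_particles)
    if isinstance(group, str):
        return ensemble.group_indices(group)
    return np.asarray(group, dtype=int)


def transition_index(frame_or_point, spec: TransitionIndexSpec, ensemble: ConformationEnsemble | None = None) -> float:
    """Scalar projection x of a conformation onto the pre→frayed axis.

    x = (d_i · d_ref) / |d_ref|^2 with d_i = r - r_pre, d_ref = r_frayed - r_pre,
    where r is the probe-group center of mass of the frame (or a bare point).
    x = 0 at the pre-translocation reference and x = 1 at the frayed
    reference; values outside [0, 1] are allowed.
    """
    d_ref = spec.r_frayed - spec.r_pre
    denom = float(d_ref @ d_ref)
    if denom == 0.0:
        raise DegenerateReferenceError("reference vector has zero length")
    point = np.asarray(frame_or_point, dtype=float)
    if point.ndim == 2:  # a full frame: take the probe group c.o.m.
        if ensemble is not None:
            idx = ensemble.group_indices(spec.probe_group)
        else:
            raise UnknownSelectionError(
                f"pass ensemble= to resolve probe group {spec.probe_group!r}"
            )
        point = point[idx].mean(axis=0)
    d_i = point - spec.r_pre
    return float(d_i @ d_ref / denom)


def transition_index_series(ensemble: ConformationEnsemble, spec: TransitionIndexSpec) -> np.ndarray:
    """Transition index of every frame (vectorized over the ensemble)."""
    d_ref = spec.r_frayed - spec.r_pre
    denom = float(d_ref @ d_ref)
    if denom == 0.0:
        raise DegenerateReferenceError("reference vector has zero length")
    com = ensemble.com(spec.probe_group)
    return (com - spec.r_pre) @ d_ref / denom


def classify_ts_ensemble(final_indices, threshold: float = 0.5) -> dict[str, float]:
    """Classify transition-state-seeded runs by their destination.

    Runs whose final transition index is below ``threshold`` returned to the
    pre-translocation side; the rest reached the frayed side. Returns the two
    fractions (they sum to 1).
    """
    x = np.asarray(list(final_indices), dtype=float)
    if x.size == 0:
        raise EmptyInputError("no final transition indices supplied")
    pre = float(np.mean(x < threshold))
    return {"pre_like": pre, "frayed_like": 1.0 - pre}


def cross_correlation_map(
    ensemble: ConformationEnsemble,
    groups: list[str],
    frame_subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Dynamic cross-correlation map between group centers of mass.

    C_ab = <Δr_a · Δr_b> / sqrt(<|Δr_a|^2><|Δr_b|^2>), where Δr is the
    displacement of the group c.o.m. from its mean over the frame subset.
    Applied per metastable state by passing that state's frames as
    ``frame_subset``. Returns a labeled symmetric matrix with unit diagonal.
    """
    if not groups:
        raise EmptyInputError("no groups supplied")
    coms = np.stack([ensemble.com(g) for g in groups], axis=1)  # (F, G, 3)
    if frame_subset is not None:
        coms = coms[np.asarray(frame_subset, dtype=int)]
    if coms.shape[0] < 2:
        raise InsufficientFramesError("cross-correlation needs at least two frames")
    delta = coms - coms.mean(axis=0)
    cov = np.einsum("fad,fbd->ab", delta, delta) / delta.shape[0]
    var = np.diag(cov)
    for g, v in zip(groups, var):
        if v <= 0.0:
            raise ZeroVarianceError(g)
    corr = cov / np.sqrt(np.outer(var, var))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=groups, columns=groups)


def distance_to_reference(
    ensemble: ConformationEnsemble,
    reference: np.ndarray,
    groups: list[str],
    average_groups: bool = False,
    reference_groups: dict[str, np.ndarray] | None = None,
    state_assignment: np.ndarray | None = None,
):
    """Per-frame distance of group centers of mass to a reference frame.

    For each frame and group, the Euclidean distance between the group
    c.o.m. and the same group's c.o.m. in ``reference``. With
    ``average_groups`` the per-frame mean over groups is returned (the
    convention used when profiling upstream hybrid positions against the
    pre-translocation structure). If ``state_assignment`` labels each frame
    with a state, a per-state mean ± SD summary table is returned alongside.
    """
    reference = np.asarray(reference, dtype=float)
    ref_groups = reference_groups if reference_groups is not None else ensemble.groups
    dists = []
    for g in groups:
        idx = ensemble.group_indices(g)
        if g not in ref_groups:
            raise UnknownSelectionError(g)
        ref_com = reference[np.asarray(ref_groups[g], dtype=int)].mean(axis=0)
        com = ensemble.coordinates[:, idx, :].mean(axis=1)
        dists.append(np.linalg.norm(com - ref_com, axis=1))
    series = np.stack(dists, axis=1)  # (F, G)
    out = series.mean(axis=1) if average_groups else series
    if state_assignment is None:
        return out
    states = np.asarray(state_assignment, dtype=int)
    per_frame = out if average_groups else out.mean(axis=1)
    rows = []
    for s in np.unique(states):
        vals = per_frame[states == s]
        rows.append({"state": int(s), "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=0)), "n_frames": int(vals.size)})
    return out, pd.DataFrame(rows)
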