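"""Microstate decomposition of trajectory frames by greedy k-centers.

The k-centers (farthest-point) algorithm picks each new cluster center as
the frame farthest from its nearest existing center; it is deterministic
given the first center and yields a 2-approximation of the optimal
k-center covering radius. Frames may be low-dimensional feature vectors
(Euclidean metric) or full coordinate frames (pairwise Kabsch RMSD
metric, used when clustering conformations directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncompatibleFramesError, InvalidKError, UnknownMetricError
from .geometry import kabsch_rmsd

__all__ = ["MicrostateDecomposition", "k_centers", "assign"]

_METRICS = ("euclidean", "rmsd")


@dataclass
class MicrostateDecomposition:
    """Result of k-centers clustering over a pooled set of trajectories.

    ``centers`` references each center as (trajectory index, frame index);
    ``center_features`` caches the centers' feature vectors (or coordinate
    frames) so that new data can be assigned without the original frames.
    """

    centers: list[tuple[int, int]]
    center_features: np.ndarray
    n_states: int
    assignments: list[np.ndarray]
    metric: str
    cluster_radii: np.ndarray

    def flat_assignments(self) -> np.ndarray:
        return np.concatenate(self.assignments)


def _as_traj_list(frames):
    if isinstance(frames, np.ndarray):
        return [frames]
    return list(frames)


def _distance_to(center: np.ndarray, frames: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.linalg.norm(frames - center, axis=1)
    # pairwise Kabsch RMSD (coordinate frames (P, 3)); loop is acceptable at
    # the frame counts where this metric is used
    return np.array([kabsch_rmsd(center, f) for f in frames])


def k_centers(
    frames,
    k: int,
    metric: str = "euclidean",
    first_center: int | None = 0,
    seed: int | None = None,
) -> MicrostateDecomposition:
    """Greedy farthest-point k-centers clustering.

    Parameters
    ----------
    frames
        One array or a list of per-trajectory arrays. For ``metric=
        "euclidean"`` rows are feature vectors; for ``metric="rmsd"``
        entries are (P, 3) coordinate frames.
    k
        Number of microstates; 1 <= k <= total frames.
    first_center
        Flat index of the first center (default 0, deterministic). Pass
        ``None`` with a ``seed`` to draw it at random for robustness studies.
    """
    if metric not in _METRICS:
        raise UnknownMetricError(f"metric {metric!r} not in {_METRICS}")
    trajs = _as_traj_list(frames)
    lengths = [len(t) for t in trajs]
    n = sum(lengths)
    if not (1 <= k <= n):
        raise InvalidKError(f"k={k} outside [1, {n}]")
    if metric == "euclidean":
        flat = np.concatenate([np.atleast_2d(np.asarray(t, dtype=float)) for t in trajs])
        if flat.ndim == 1:
            flat = flat[:, None]
    else:
        flat = np.concatenate([np.asarray(t, dtype=float) for t in trajs])
        flat = flat.reshape(n, *trajs[0].shape[1:])
    if first_center is None:
        first = int(np.random.default_rng(seed).integers(n))
    else:
        first = int(first_center)

    center_idx = [first]
    dist = _distance_to(flat[first], flat, metric)
    labels = np.zeros(n, dtype=np.int64)
    for c in range(1, k):
        nxt = int(np.argmax(dist))
        center_idx.append(nxt)
        d_new = _distance_to(flat[nxt], flat, metric)
        closer = d_new < dist
        labels[closer] = c
        dist = np.minimum(dist, d_new)

    radii = np.zeros(k)
    for c in range(k):
        members = dist[labels == c]
        radii[c] = members.max() if members.size else 0.0

    offsets = np.cumsum([0] + lengths)
    centers = []
    for ci in center_idx:
        ti = int(np.searchsorted(offsets, ci, side="right") - 1)
        centers.append((ti, int(ci - offsets[ti])))
    assignments = [labels[offsets[i]:offsets[i + 1]].copy() for i in range(len(trajs))]
    return MicrostateDecomposition(
        centers=centers,
        center_features=flat[center_idx].copy(),
        n_states=k,
        assignments=assignments,
        metric=metric,
        cluster_radii=radii,
    )


def assign(frames, decomposition: MicrostateDecomposition) -> np.ndarray:
    """Nearest-center label for new frames; ties break to the lower index."""
    trajs = _as_traj_list(frames)
    if decomposition.metric == "euclidean":
        flat = np.concatenate([np.atleast_2d(np.asarray(t, dtype=float)) for t in trajs])
        if flat.ndim == 1:
            flat = flat[:, None]
        if flat.shape[1] != decomposition.center_features.shape[1]:
            raise IncompatibleFramesError(
                f"frames have dimension {flat.shape[1]}, "
                f"centers {decomposition.center_features.shape[1]}"
            )
        d = np.linalg.norm(flat[:, None, :] - decomposition.center_features[None], axis=2)
    else:
        flat = np.concatenate([np.asarray(t, dtype=float) for t in trajs])
        if flat.shape[1:] != decomposition.center_features.shape[1:]:
            raise IncompatibleFramesError("coordinate frames incompatible with centers")
        d = np.stack(
            [_distance_to(c, flat, "rmsd") for c in decomposition.center_features], axis=1
        )
    return np.argmin(d, axis=1).astype(np.int64)
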