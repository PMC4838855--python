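"""Readers and writers for pipeline artifacts.

Plain-text formats throughout: XYZ for pseudo-particle trajectories (with
a flat binary array + JSON sidecar alternative), single-column integer
text for discrete trajectories, JSON for chains, models, lumpings,
pathways and reports, CSV (with state/group headers) for matrices and
tidy observable tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .discretize import MicrostateDecomposition
from .geometry import ConformationEnsemble
from .synthetic import GroundTruthChain

__all__ = [
    "write_xyz", "read_xyz",
    "write_ensemble_binary", "read_ensemble_binary",
    "write_discrete", "read_discrete",
    "write_chain", "read_chain",
    "write_matrix_csv", "read_matrix_csv",
    "write_decomposition", "write_lumping", "write_json", "read_json",
]


def write_xyz(path, ensemble: ConformationEnsemble, comment: str = "") -> None:
    """One XYZ block per frame; the element column carries particle labels."""
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_particles}\n")
            fh.write(f"frame {f} t={f * ensemble.frame_interval:.6g} ns {comment}\n")
            for lab, (x, y, z) in zip(ensemble.labels, ensemble.coordinates[f]):
                fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path, frame_interval: float = 1.0) -> ConformationEnsemble:
    frames, labels = [], None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        labs, coords = [], []
        for row in block:
            parts = row.split()
            labs.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if labels is None:
            labels = labs
        frames.append(coords)
        i += 2 + n
    return ConformationEnsemble(np.array(frames), labels, frame_interval=frame_interval)


def write_ensemble_binary(prefix, ensemble: ConformationEnsemble) -> None:
    """Flat float64 binary + JSON sidecar (shape, labels, frame interval)."""
    prefix = Path(prefix)
    ensemble.coordinates.astype(np.float64).tofile(prefix.with_suffix(".bin"))
    sidecar = {
        "shape": list(ensemble.coordinates.shape),
        "dtype": "float64",
        "labels": ensemble.labels,
        "frame_interval_ns": ensemble.frame_interval,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_ensemble_binary(prefix) -> ConformationEnsemble:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    coords = np.fromfile(prefix.with_suffix(".bin"), dtype=meta["dtype"])
    coords = coords.reshape(meta["shape"])
    return ConformationEnsemble(coords, meta["labels"],
                                frame_interval=meta["frame_interval_ns"])


def write_discrete(path, traj: np.ndarray) -> None:
    np.savetxt(path, np.asarray(traj, dtype=np.int64), fmt="%d")


def read_discrete(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int64).reshape(-1)


def write_chain(path, chain: GroundTruthChain) -> None:
    doc = {
        "transition_matrix": chain.transition_matrix.tolist(),
        "lag_duration_ns": chain.lag_duration,
        "state_labels": None if chain.state_labels is None else chain.state_labels.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_chain(path) -> GroundTruthChain:
    doc = json.loads(Path(path).read_text())
    return GroundTruthChain(
        np.array(doc["transition_matrix"]),
        lag_duration=doc["lag_duration_ns"],
        state_labels=doc["state_labels"],
    )


def write_matrix_csv(path, matrix: np.ndarray, labels=None) -> None:
    m = np.asarray(matrix)
    labels = labels if labels is not None else [str(i) for i in range(m.shape[0])]
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path)


def read_matrix_csv(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy()


def write_decomposition(path, dec: MicrostateDecomposition) -> None:
    doc = {
        "n_states": dec.n_states,
        "metric": dec.metric,
        "centers": [[int(t), int(f)] for t, f in dec.centers],
        "cluster_radii": dec.cluster_radii.tolist(),
        "center_features": dec.center_features.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_lumping(path, lumping) -> None:
    doc = {
        "n_macro": lumping.n_macro,
        "macro_labels": lumping.macro_labels,
        "crisp_assignment": lumping.crisp_assignment.tolist(),
        "membership": lumping.membership.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
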