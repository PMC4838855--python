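"""Synthetic trajectory generators with known ground truth.

The estimation pipeline in this package (clustering → Markov model →
PCCA+ → kinetics → flux) is validated on data whose answers are known
exactly. Two generators provide that data:

* an overdamped Langevin sampler on a 2-D multi-well free-energy
  landscape, with a four-well builder whose wells sit on an arc so that a
  stepwise channel (1→2→3→4) and a direct 1↔4 channel are geometrically
  distinct, emulating pre-translocation → frayed → intermediate →
  backtracked kinetics with short trajectory swarms seeded along an
  initial pathway;
* a discrete ground-truth Markov chain sampler, including a block-chain
  builder with four metastable blocks and one rate-limiting inter-block
  coupling, for which stationary populations, implied timescales and
  MFPTs are computable exactly by linear algebra.

Every landscape frame is also emitted as six labeled pseudo-particles
(RNA 3'-end, DNA transition nucleotide, and the T831/T827/Y836/Y769
residue analogues) placed by fixed affine maps of the landscape
coordinates plus seeded isotropic noise, so the geometric observables
(transition index, DCCM, distance-to-reference) are exercisable.

All generators are bitwise reproducible under a fixed seed; swarm members
derive their seeds from the master seed and the start index via
``numpy.random.SeedSequence([seed, index])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    IntegrationBlowupError,
    InvalidChainError,
    InvalidCorrelationError,
    InvalidParameterError,
)
from .geometry import ConformationEnsemble

__all__ = [
    "MultiWellLandscape",
    "LangevinParams",
    "GroundTruthChain",
    "build_four_well",
    "simulate_langevin",
    "seed_from_path",
    "seed_polyline_swarm",
    "sample_chain",
    "sample_chain_swarm",
    "correlated_displacements",
    "build_block_chain",
    "PSEUDO_PARTICLE_LABELS",
]

# Pseudo-particle analogues of the structural elements tracked by the
# geometric observables. DNA_TN is the transition-index probe group.
PSEUDO_PARTICLE_LABELS = ["RNA3", "DNA_TN", "T831", "T827", "Y836", "Y769"]

# Fixed affine maps (A: 3x2, b: 3) embedding the 2-D landscape coordinate
# into each pseudo-particle's 3-D position. DNA_TN is the identity embed so
# the transition index reads the landscape progression directly.
_AFFINE_MAPS = [
    (np.array([[0.9, 0.1], [-0.2, 0.8], [0.3, 0.2]]), np.array([0.5, -0.2, 0.1])),   # RNA3
    (np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]), np.array([0.0, 0.0, 0.0])),     # DNA_TN
    (np.array([[0.4, -0.3], [0.5, 0.5], [-0.2, 0.6]]), np.array([-0.4, 0.3, 0.2])),  # T831
    (np.array([[0.2, 0.5], [-0.4, 0.3], [0.6, -0.1]]), np.array([0.2, 0.6, -0.3])),  # T827
    (np.array([[-0.5, 0.4], [0.3, -0.6], [0.1, 0.5]]), np.array([0.7, 0.1, 0.4])),   # Y836
    (np.array([[0.6, 0.2], [0.2, -0.5], [-0.4, 0.3]]), np.array([-0.1, -0.5, 0.6])), # Y769
]

_PSEUDO_NOISE_SIGMA = 0.02  # nm, isotropic per-particle jitter


@dataclass(frozen=True)
class MultiWellLandscape:
    """Sum-of-inverted-Gaussians free-energy landscape in 2-D.

    U(p) = -sum_w depth_w * exp(-|p - center_w|^2 / (2 width_w^2))
           + sum_b height_b * exp(-|p - bump_b|^2 / (2 bump_width_b^2))

    ``barriers`` raise the direct channel between a pair of wells with a
    Gaussian bump midway between their centers.
    """

    centers: np.ndarray          # (n_wells, 2)
    depths: np.ndarray           # kT
    widths: np.ndarray           # nm
    barriers: tuple = ()         # ((i, j, height, bump_width), ...)
    # smooth quartic confining wall: zero inside `confine_radius` of
    # `confine_center`, rising as strength*(r-radius)^4 outside, so walkers
    # cannot diffuse away from the well region (Gaussian wells alone are
    # non-confining)
    confine_center: np.ndarray | None = None
    confine_radius: float = 0.0
    confine_strength: float = 0.0
    # arc corridor: everything farther than ~band from the circular arc
    # (center, radius, theta range) is raised by `height`, so the only
    # low-energy channel between the endpoint wells is the stepwise arc;
    # tuple (cx, cy, radius, theta_min, theta_max, band, height)
    arc_corridor: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "centers", np.atleast_2d(np.asarray(self.centers, dtype=float)))
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        object.__setattr__(self, "widths", np.asarray(self.widths, dtype=float))
        if self.centers.shape[0] < 2:
            raise InvalidParameterError("need at least 2 wells")
        if np.any(self.depths <= 0) or np.any(self.widths <= 0):
            raise InvalidParameterError("depths and widths must be positive")
        d = np.linalg.norm(self.centers[:, None] - self.centers[None, :], axis=2)
        if np.any(d[np.triu_indices(len(d), 1)] == 0):
            raise InvalidParameterError("well centers must be pairwise distinct")
        if self.confine_center is not None:
            object.__setattr__(self, "confine_center",
                               np.asarray(self.confine_center, dtype=float))

    @property
    def n_wells(self) -> int:
        return self.centers.shape[0]

    def _bumps(self):
        for (i, j, h, w) in self.barriers:
            yield (self.centers[i] + self.centers[j]) / 2.0, h, w

    def _arc_distance(self, p: np.ndarray) -> np.ndarray:
        """Distance from points (n, 2) to the corridor arc."""
        cx, cy, R, th_min, th_max, band, height = self.arc_corridor
        rel = p - np.array([cx, cy])
        r = np.linalg.norm(rel, axis=1)
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        inside = (theta >= th_min) & (theta <= th_max)
        # within the angular span: radial distance to the circle; outside:
        # distance to the nearest arc endpoint
        e1 = np.array([cx + R * np.cos(th_min), cy + R * np.sin(th_min)])
        e2 = np.array([cx + R * np.cos(th_max), cy + R * np.sin(th_max)])
        d_end = np.minimum(np.linalg.norm(p - e1, axis=1),
                           np.linalg.norm(p - e2, axis=1))
        return np.where(inside, np.abs(r - R), d_end)

    def potential(self, points: np.ndarray) -> np.ndarray:
        """U at one point (2,) or many points (..., 2), in kT."""
        p = np.asarray(points, dtype=float)
        scalar = p.ndim == 1
        p = np.atleast_2d(p)
        d2 = np.sum((p[:, None, :] - self.centers[None, :, :]) ** 2, axis=2)
        u = -(self.depths * np.exp(-d2 / (2.0 * self.widths**2))).sum(axis=1)
        for c, h, w in self._bumps():
            u = u + h * np.exp(-np.sum((p - c) ** 2, axis=1) / (2.0 * w**2))
        if self.arc_corridor is not None:
            band, height = self.arc_corridor[5], self.arc_corridor[6]
            d = self._arc_distance(p)
            u = u + height * (1.0 - np.exp(-d**2 / (2.0 * band**2)))
        if self.confine_center is not None:
            r = np.linalg.norm(p - self.confine_center, axis=1)
            u = u + self.confine_strength * np.clip(r - self.confine_radius, 0.0, None) ** 4
        return float(u[0]) if scalar else u

    def gradient(self, point: np.ndarray) -> np.ndarray:
        """∇U at a single 2-D point, kT/nm."""
        p = np.asarray(point, dtype=float)
        diff = p - self.centers                                    # (n_wells, 2)
        d2 = np.sum(diff**2, axis=1)
        g = (self.depths / self.widths**2 * np.exp(-d2 / (2.0 * self.widths**2))) @ diff
        for c, h, w in self._bumps():
            dc = p - c
            g = g - h / w**2 * np.exp(-dc @ dc / (2.0 * w**2)) * dc
        if self.arc_corridor is not None:
            cx, cy, R, th_min, th_max, band, height = self.arc_corridor
            rel = p - np.array([cx, cy])
            r = np.linalg.norm(rel)
            theta = np.arctan2(rel[1], rel[0])
            if th_min <= theta <= th_max:
                d = r - R
                grad_d = rel / r if r > 0 else np.zeros(2)
                d_abs = abs(d)
                grad_d = grad_d * np.sign(d)
            else:
                e1 = np.array([cx + R * np.cos(th_min), cy + R * np.sin(th_min)])
                e2 = np.array([cx + R * np.cos(th_max), cy + R * np.sin(th_max)])
                de1, de2 = np.linalg.norm(p - e1), np.linalg.norm(p - e2)
                e = e1 if de1 <= de2 else e2
                d_abs = min(de1, de2)
                grad_d = (p - e) / d_abs if d_abs > 0 else np.zeros(2)
            g = g + height * np.exp(-d_abs**2 / (2.0 * band**2)) * (d_abs / band**2) * grad_d
        if self.confine_center is not None:
            dc = p - self.confine_center
            r = np.linalg.norm(dc)
            excess = r - self.confine_radius
            if excess > 0 and r > 0:
                g = g + 4.0 * self.confine_strength * excess**3 * dc / r
        return g

    def basin_labels(self, points: np.ndarray) -> np.ndarray:
        """Ground-truth basin label: index of the nearest well center."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = np.sum((p[:, None, :] - self.centers[None, :, :]) ** 2, axis=2)
        return np.argmin(d2, axis=1)


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped (Euler–Maruyama) integrator parameters.

    The integrator is stable for ``timestep <= width^2 * friction /
    (4 * max depth)`` (harmonic estimate at the stiffest well); the
    default four-well landscape with friction 1 admits dt = 0.002.
    """

    timestep: float
    n_steps: int
    friction: float = 1.0
    kT: float = 1.0
    save_stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise InvalidParameterError("timestep must be positive")
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.save_stride < 1:
            raise InvalidParameterError("save_stride must be >= 1")
        if self.kT < 0:
            raise InvalidParameterError("kT must be >= 0")
        if self.friction <= 0:
            raise InvalidParameterError("friction must be positive")


@dataclass(frozen=True)
class GroundTruthChain:
    """Known transition matrix used as an oracle for the estimators."""

    transition_matrix: np.ndarray
    lag_duration: float = 1.0     # ns per chain step
    state_labels: np.ndarray | None = None  # optional macro label per state

    def __post_init__(self):
        T = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "transition_matrix", T)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise InvalidChainError("transition matrix must be square")
        if np.any(T < 0) or np.any(T > 1):
            raise InvalidChainError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-9:
            raise InvalidChainError("rows must sum to 1 (tolerance 1e-9)")
        if self.state_labels is not None:
            object.__setattr__(self, "state_labels", np.asarray(self.state_labels, dtype=int))

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary(self) -> np.ndarray:
        """Exact stationary distribution (leading left eigenvector)."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = np.argmin(np.abs(w - 1.0))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def build_four_well(
    spacing: float = 1.0,
    depths=(5.0, 4.0, 4.5, 6.0),
    widths=(0.25, 0.25, 0.25, 0.25),
    direct_barrier: float = 8.0,
) -> MultiWellLandscape:
    """Four wells on an arc with a raised direct channel between wells 1 and 4.

    Consecutive wells are ``spacing`` apart (chord length); the arc spans
    120° so wells 1 and 4 are ~2.5 spacings apart, and a Gaussian bump of
    height ``direct_barrier`` midway between them blocks the direct (concerted)
    channel, leaving the stepwise channel along the arc. The default depths
    make well 4 the deepest, mirroring the backtracked state being the most
    stable, with a shallow intermediate (well 3).
    """
    depths = np.asarray(depths, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if spacing <= 0 or np.any(depths <= 0) or np.any(widths <= 0) or direct_barrier < 0:
        raise InvalidParameterError("spacing, depths, widths must be positive")
    dtheta = np.deg2rad(40.0)
    radius = spacing / (2.0 * np.sin(dtheta / 2.0))
    angles = np.deg2rad(150.0) - dtheta * np.arange(4)
    centers = radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    corridor = None
    if direct_barrier > 0:
        # everything off the stepwise arc — including the straight chord
        # between wells 1 and 4 — is raised by direct_barrier, so the only
        # low-energy channel is the stepwise one
        corridor = (0.0, 0.0, float(radius),
                    float(angles[3]), float(angles[0]),
                    float(1.2 * widths.max()), float(direct_barrier))
    # wall hugs the well region: flat plateaus outside the wells would
    # otherwise form spurious entropic metastable states
    centroid = centers.mean(axis=0)
    wall_radius = float(np.max(np.linalg.norm(centers - centroid, axis=1)) + widths.max())
    return MultiWellLandscape(centers, depths, widths, barriers=(),
                              confine_center=centroid, confine_radius=wall_radius,
                              confine_strength=100.0, arc_corridor=corridor)


def _pseudo_particles(path: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Embed a (F, 2) landscape path as (F, 6, 3) pseudo-particle coordinates."""
    frames = np.empty((path.shape[0], len(_AFFINE_MAPS), 3))
    for k, (A, b) in enumerate(_AFFINE_MAPS):
        frames[:, k, :] = path @ A.T + b
    frames += rng.normal(0.0, _PSEUDO_NOISE_SIGMA, size=frames.shape)
    return frames


def pseudo_particle_positions(point: np.ndarray) -> np.ndarray:
    """Noise-free pseudo-particle positions (6, 3) of a single landscape point."""
    p = np.asarray(point, dtype=float)
    return np.stack([A @ p + b for A, b in _AFFINE_MAPS])


def simulate_langevin(
    landscape: MultiWellLandscape,
    params: LangevinParams,
    start: np.ndarray,
) -> ConformationEnsemble:
    """Overdamped Langevin (Euler–Maruyama) trajectory on the landscape.

    Update: p <- p - ∇U Δt/γ + sqrt(2 kT Δt/γ) η with η standard normal per
    dimension. Frames (including the initial point) are recorded every
    ``save_stride`` steps. The returned ensemble carries the raw landscape
    path in ``reaction_coords`` and the six pseudo-particles as coordinates.
    Identical seed ⇒ identical trajectory bitwise.
    """
    p = np.asarray(start, dtype=float).copy()
    if p.shape != (2,) or not np.isfinite(p).all():
        raise InvalidParameterError("start must be a finite 2-D point")
    rng = np.random.default_rng(params.seed)
    dt, gamma, kT = params.timestep, params.friction, params.kT
    noise_scale = np.sqrt(2.0 * kT * dt / gamma)
    # all noise drawn up front in one call: keeps the consumption order
    # independent of save_stride and lets kT=0 short-circuit cleanly
    noise = rng.normal(size=(params.n_steps, 2)) * noise_scale if kT > 0 else None
    n_saved = params.n_steps // params.save_stride + 1
    path = np.empty((n_saved, 2))
    path[0] = p
    isave = 1
    for step in range(params.n_steps):
        p = p - landscape.gradient(p) * (dt / gamma)
        if noise is not None:
            p = p + noise[step]
        if not np.isfinite(p).all():
            raise IntegrationBlowupError(step)
        if (step + 1) % params.save_stride == 0:
            path[isave] = p
            isave += 1
    path = path[:isave]
    prng = np.random.default_rng(np.random.SeedSequence([int(params.seed) % (2**31), 7]))
    return ConformationEnsemble(
        coordinates=_pseudo_particles(path, prng),
        labels=list(PSEUDO_PARTICLE_LABELS),
        frame_interval=params.timestep * params.save_stride,
        reaction_coords=path,
    )


def _child_params(params: LangevinParams, index: int) -> LangevinParams:
    child = np.random.SeedSequence([int(params.seed) % (2**31), int(index)])
    seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
    return LangevinParams(
        timestep=params.timestep, n_steps=params.n_steps, friction=params.friction,
        kT=params.kT, save_stride=params.save_stride, seed=seed,
    )


def seed_from_path(
    landscape: MultiWellLandscape,
    endpoints: np.ndarray,
    n_interp: int,
    params: LangevinParams,
) -> list[ConformationEnsemble]:
    """Swarm of short simulations seeded along a straight initial pathway.

    Launches one simulation from each of ``n_interp`` points linearly
    interpolated between the two endpoints (endpoints included); per-member
    seeds derive deterministically from ``params.seed`` and the start index.
    """
    if n_interp < 2:
        raise InvalidParameterError("n_interp must be >= 2")
    a, b = (np.asarray(e, dtype=float) for e in endpoints)
    fracs = np.linspace(0.0, 1.0, n_interp)
    return [
        simulate_langevin(landscape, _child_params(params, i), a + f * (b - a))
        for i, f in enumerate(fracs)
    ]


def seed_polyline_swarm(
    landscape: MultiWellLandscape,
    n_per_segment: int,
    params: LangevinParams,
    well_order: tuple = None,
) -> list[ConformationEnsemble]:
    """Swarm seeded along the polyline through the well centers (stepwise pathway).

    One :func:`seed_from_path` call per consecutive well pair; member seeds
    stay distinct across segments via an index offset.
    """
    order = tuple(range(landscape.n_wells)) if well_order is None else tuple(well_order)
    swarm = []
    for s in range(len(order) - 1):
        a = landscape.centers[order[s]]
        b = landscape.centers[order[s + 1]]
        fracs = np.linspace(0.0, 1.0, n_per_segment)
        for i, f in enumerate(fracs):
            idx = s * n_per_segment + i
            swarm.append(
                simulate_langevin(landscape, _child_params(params, idx), a + f * (b - a))
            )
    return swarm


# ---------------------------------------------------------------------------
# discrete ground-truth chains


def sample_chain(
    chain: GroundTruthChain,
    n_steps: int,
    start: int,
    seed: int = 0,
) -> np.ndarray:
    """Sample a discrete trajectory of ``n_steps + 1`` states from the chain."""
    T = chain.transition_matrix
    n = chain.n_states
    if not (0 <= start < n):
        raise InvalidParameterError(f"start state {start} outside [0, {n})")
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps)
    out = np.empty(n_steps + 1, dtype=np.int64)
    out[0] = s = start
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        out[t + 1] = s
    return out


def sample_chain_swarm(
    chain: GroundTruthChain,
    n_trajs: int,
    n_steps: int,
    starts="stationary",
    seed: int = 0,
) -> list[np.ndarray]:
    """Sample many trajectories at once (vectorized across the swarm).

    ``starts`` may be an integer array of start states, or "stationary" to
    draw starts from the chain's exact stationary distribution (equilibrium
    sampling conditions).
    """
    T = chain.transition_matrix
    rng = np.random.default_rng(seed)
    if isinstance(starts, str) and starts == "stationary":
        pi = chain.stationary()
        state = rng.choice(chain.n_states, size=n_trajs, p=pi).astype(np.int64)
    else:
        state = np.asarray(starts, dtype=np.int64).copy()
        if state.shape != (n_trajs,):
            raise InvalidParameterError("starts must have one entry per trajectory")
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    out = np.empty((n_trajs, n_steps + 1), dtype=np.int64)
    out[:, 0] = state
    for t in range(n_steps):
        u = rng.random(n_trajs)
        state = (cum[state] < u[:, None]).sum(axis=1)
        out[:, t + 1] = state
    return [out[i] for i in range(n_trajs)]


def correlated_displacements(
    correlation: np.ndarray,
    n_frames: int,
    seed: int = 0,
) -> ConformationEnsemble:
    """Gaussian pseudo-particle ensemble with prescribed pairwise correlation.

    Per-frame positions are zero-mean Gaussians with unit variance per
    spatial component, generated by applying a matrix square root of the
    correlation matrix to independent normals, identically across the three
    spatial components. The resulting DCCM converges to ``correlation``.
    """
    C = np.asarray(correlation, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise InvalidCorrelationError("correlation must be a square matrix")
    if not np.allclose(C, C.T, atol=1e-12):
        raise InvalidCorrelationError("correlation must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-12):
        raise InvalidCorrelationError("correlation must have unit diagonal")
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-10:
        raise InvalidCorrelationError(f"correlation not PSD (min eigenvalue {w.min():.3e})")
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    m = C.shape[0]
    rng = np.random.default_rng(seed)
    coords = np.einsum("fdk,mk->fmd", rng.normal(size=(n_frames, 3, m)), L)
    labels = [f"P{i}" for i in range(m)]
    return ConformationEnsemble(coordinates=coords, labels=labels)


def build_block_chain(
    block_sizes=(5, 5, 5, 5),
    block_strengths=(0.105, 0.224, 0.040, 0.631),
    couplings=(0.02, 0.01, 0.008),
    lag_duration: float = 1.0,
    jitter: float = 0.15,
    seed: int = 0,
) -> GroundTruthChain:
    """Metastable block chain: n blocks in a line with one slow bottleneck.

    Built from a symmetric weight matrix W (complete graph within each
    block scaled by that block's strength, single bridge edges between
    consecutive blocks) and row-normalized, so the chain is reversible with
    exact stationary distribution proportional to the row sums of W. The
    default strengths are proportional to the four metastable-state
    populations of the system being emulated (10.5/22.4/4.0/63.1 %), and
    the weakest coupling sits on the 3↔4 bond so the last transition is
    rate-limiting. ``jitter`` perturbs within-block weights (seeded) to
    avoid exact spectral degeneracies.
    """
    sizes = tuple(int(s) for s in block_sizes)
    n = sum(sizes)
    strengths = np.asarray(block_strengths, dtype=float)
    coup = np.asarray(couplings, dtype=float)
    if len(sizes) < 2 or len(strengths) != len(sizes) or len(coup) != len(sizes) - 1:
        raise InvalidParameterError("need one strength per block and one coupling per bond")
    if np.any(strengths <= 0) or np.any(coup <= 0):
        raise InvalidParameterError("strengths and couplings must be positive")
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    offsets = np.cumsum((0,) + sizes)
    labels = np.empty(n, dtype=int)
    for b, size in enumerate(sizes):
        lo, hi = offsets[b], offsets[b + 1]
        labels[lo:hi] = b
        block = strengths[b] * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=(size, size)))
        block = (block + block.T) / 2.0
        W[lo:hi, lo:hi] = np.abs(block)
    for b in range(len(sizes) - 1):
        i = offsets[b + 1] - 1   # last state of block b
        j = offsets[b + 1]       # first state of block b+1
        W[i, j] = W[j, i] = coup[b]
    T = W / W.sum(axis=1, keepdims=True)
    return GroundTruthChain(T, lag_duration=lag_duration, state_labels=labels)
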