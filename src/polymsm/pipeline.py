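"""End-to-end pipeline: generate → discretize → estimate → validate →
lump → kinetics → flux → observables → report.

A single :class:`PipelineConfig` drives the whole analysis; one
invocation writes a content-addressed run directory (config hash) holding
every intermediate artifact, so every number in the final report is
recomputable from persisted intermediates. All times are stored in ns
internally; the human-readable kinetics table converts to the unit
requested in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .discretize import k_centers
from .errors import PipelineConfigError, IncompleteRunError, PolymsmError
from .geometry import (
    TransitionIndexSpec,
    cross_correlation_map,
    distance_to_reference,
    transition_index_series,
)
from .kinetics import bootstrap_kinetics
from .macrostates import macro_populations, pcca_plus, sort_macrostates
from .msm import (
    count_transitions,
    estimate_transition_matrix,
    implied_timescales,
    residence_probability_test,
    trim_to_ergodic,
)
from .synthetic import (
    LangevinParams,
    build_block_chain,
    build_four_well,
    pseudo_particle_positions,
    sample_chain_swarm,
    seed_polyline_swarm,
)
from .tpt import decompose_pathways, mechanism_fraction, reactive_flux

logger = logging.getLogger("polymsm.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "validate_report", "load_config"]


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    ``source`` selects the input: "four_well" (Langevin swarm on the
    four-well landscape), "block_chain" (discrete ground-truth chain
    swarm), or "discrete_paths" (pre-discretized integer trajectories from
    files). Defaults encode the reference protocol of the system being
    emulated at desk scale: k = 100 microstates, 4 macrostates, lag chosen
    from a candidate ladder, reversible estimator, B = 100 bootstrap
    resamples.
    """

    source: str = "four_well"
    seed: int = 0
    # four-well generator
    n_per_segment: int = 14
    n_steps: int = 5000
    timestep: float = 0.002
    friction: float = 1.0
    kT: float = 0.8
    save_stride: int = 1
    direct_barrier: float = 8.0
    # block-chain generator
    chain_n_trajs: int = 100
    chain_n_steps: int = 2000
    # discrete input
    trajectory_paths: list[str] = field(default_factory=list)
    frame_interval: float = 1.0
    # discretization
    k: int = 100
    metric: str = "euclidean"
    # estimation
    lags: list[int] = field(default_factory=lambda: [1, 5, 10, 20, 40])
    lag: int = 20
    reversible: bool = True
    n_timescales: int = 5
    # lumping / kinetics / flux
    n_macro: int = 4
    bootstrap_B: int = 100
    source_macro: str = "S1"
    sink_macro: str = "S4"
    stepwise_macros: list[str] = field(default_factory=lambda: ["S2", "S3"])
    mfpt_unit: str = "us"
    # observables
    observables: bool = True

    def validate(self) -> None:
        if self.source not in ("four_well", "block_chain", "discrete_paths"):
            raise PipelineConfigError(f"unknown source {self.source!r}")
        if self.k < self.n_macro:
            raise PipelineConfigError(f"k={self.k} < n_macro={self.n_macro}")
        if self.lag not in self.lags:
            raise PipelineConfigError(f"chosen lag {self.lag} not among candidates {self.lags}")
        if self.source == "discrete_paths":
            missing = [p for p in self.trajectory_paths if not Path(p).exists()]
            if missing:
                raise PipelineConfigError(f"missing trajectory files: {missing}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**doc)


_MFPT_SCALE = {"ns": 1.0, "us": 1e-3, "ms": 1e-6}


class _Run:
    """Stage runner: logs timings, persists partial artifacts on failure."""

    def __init__(self, run_dir: Path):
        self.run_dir = run_dir
        self.log_path = run_dir / "run.log"
        self.timings = {}

    def log(self, msg: str):
        logger.info(msg)
        with open(self.log_path, "a") as fh:
            fh.write(msg + "\n")

    def stage(self, name):
        run = self

        class _Stage:
            def __enter__(self):
                run.log(f"stage {name}: start")
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is None:
                    run.timings[name] = dt
                    run.log(f"stage {name}: done in {dt:.2f}s")
                else:
                    run.log(f"stage {name}: FAILED ({exc}); partial artifacts preserved")
                return False

        return _Stage()


def run_pipeline(config: PipelineConfig, base_dir="runs", max_stage: str = "report") -> Path:
    """Execute the full analysis; returns the run directory.

    The run directory is content-addressed by the config hash, so re-running
    an identical config overwrites the same directory with byte-identical
    results (all randomness derives from ``config.seed``).
    """
    config.validate()
    run_dir = Path(base_dir) / f"run-{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    run = _Run(run_dir)
    run.log(f"polymsm run {config.config_hash()} seed={config.seed}")

    stages = ["generate", "discretize", "estimate", "its", "lump",
              "kinetics", "flux", "observables", "report"]
    last = stages.index(max_stage)

    ensembles = None
    landscape = None
    frame_interval = config.frame_interval

    with run.stage("generate"):
        if config.source == "four_well":
            landscape = build_four_well(direct_barrier=config.direct_barrier)
            params = LangevinParams(
                timestep=config.timestep, n_steps=config.n_steps,
                friction=config.friction, kT=config.kT,
                save_stride=config.save_stride, seed=config.seed,
            )
            ensembles = seed_polyline_swarm(landscape, config.n_per_segment, params)
            frame_interval = ensembles[0].frame_interval
            feats = [e.reaction_coords for e in ensembles]
            np.savetxt(run_dir / "reaction_coords.csv",
                       np.concatenate(feats), delimiter=",", header="x,y", comments="")
            pio.write_xyz(run_dir / "swarm_member0.xyz", ensembles[0])
        elif config.source == "block_chain":
            chain = build_block_chain(seed=config.seed)
            pio.write_chain(run_dir / "ground_truth_chain.json", chain)
            dtrajs = sample_chain_swarm(chain, config.chain_n_trajs,
                                        config.chain_n_steps, seed=config.seed)
            frame_interval = chain.lag_duration
        else:
            dtrajs = [pio.read_discrete(p) for p in config.trajectory_paths]
    if last < 1:
        return run_dir

    with run.stage("discretize"):
        if config.source == "four_well":
            dec = k_centers(feats, k=config.k, metric=config.metric)
            dtrajs = dec.assignments
            pio.write_decomposition(run_dir / "decomposition.json", dec)
        tdir = run_dir / "dtrajs"
        tdir.mkdir(exist_ok=True)
        for i, t in enumerate(dtrajs):
            pio.write_discrete(tdir / f"traj_{i:04d}.txt", t)
    if last < 2:
        return run_dir

    with run.stage("estimate"):
        cm = count_transitions(dtrajs, lag=config.lag, frame_interval=frame_interval)
        trimmed, kept = trim_to_ergodic(cm)
        model = estimate_transition_matrix(trimmed, reversible=config.reversible)
        model.state_map = kept
        pio.write_matrix_csv(run_dir / "counts.csv", cm.counts)
        pio.write_matrix_csv(run_dir / "transition_matrix.csv",
                             model.transition_matrix, labels=[str(s) for s in kept])
        pio.write_json(run_dir / "model.json", {
            "lag": config.lag, "lag_time_ns": model.lag_time,
            "estimator": model.estimator, "n_states": model.n_states,
            "kept_states": kept, "stationary": model.stationary,
            "eigenvalues": np.real(model.eigenvalues[:config.n_timescales + 1]),
            "matrix_path": "transition_matrix.csv",
        })
        # remap trajectories into model state indices for validation stages
        remap = np.full(cm.n_states, -1, dtype=np.int64)
        remap[kept] = np.arange(kept.size)
        model_trajs = [remap[t] for t in dtrajs]
        model_trajs = [t[t >= 0] for t in model_trajs]
    if last < 3:
        return run_dir

    with run.stage("its"):
        its = implied_timescales(dtrajs, config.lags, n_timescales=config.n_timescales,
                                 frame_interval=frame_interval, reversible=config.reversible)
        its.to_csv(run_dir / "implied_timescales.csv", index=False)
        top = model.stationary.argsort()[::-1][:min(5, model.n_states)]
        res = residence_probability_test(model, model_trajs, multiples=[1, 2, 5],
                                         states=list(top))
        res.to_csv(run_dir / "residence.csv", index=False)
    if last < 4:
        return run_dir

    with run.stage("lump"):
        lump = pcca_plus(model, config.n_macro)
        if config.source == "four_well":
            prog = _pathway_progress(landscape, dec.center_features[kept])
        else:
            prog = kept.astype(float)  # block chains are already pathway-ordered
        lump = sort_macrostates(lump, prog)
        pio.write_lumping(run_dir / "lumping.json", lump)
        pops = macro_populations(model.stationary, lump)
        pd.DataFrame({"macrostate": lump.macro_labels,
                      "population": pops}).to_csv(run_dir / "macro_populations.csv",
                                                  index=False)
    if last < 5:
        return run_dir

    with run.stage("kinetics"):
        report = bootstrap_kinetics(
            model_trajs, B=config.bootstrap_B, seed=config.seed, lag=config.lag,
            frame_interval=frame_interval, n_macro=config.n_macro,
            reversible=config.reversible, lumping=lump,
        )
        scale = _MFPT_SCALE.get(config.mfpt_unit, 1.0)
        pio.write_json(run_dir / "kinetics.json", {
            "macro_labels": report.macro_labels,
            "population_mean_pct": report.population_mean,
            "population_sd_pct": report.population_sd,
            "mfpt_mean_ns": report.mfpt_mean,
            "mfpt_sd_ns": report.mfpt_sd,
            "n_bootstrap": report.n_bootstrap,
            "n_failed": report.n_failed,
            "lag_time_ns": report.lag_time,
        })
        unit = {"us": "μs", "ms": "ms", "ns": "ns"}[config.mfpt_unit]
        (run_dir / "kinetics.txt").write_text(
            "\n".join(report.format_lines(mfpt_unit=unit, mfpt_scale=scale)) + "\n")
    if last < 6:
        return run_dir

    with run.stage("flux"):
        labels = lump.macro_labels
        src_label = config.source_macro if config.source_macro in labels else labels[0]
        snk_label = config.sink_macro if config.sink_macro in labels else labels[-1]
        A = lump.members(labels.index(src_label))
        B = lump.members(labels.index(snk_label))
        net = reactive_flux(model, A, B)
        edges = np.argwhere(net.net_flux > 0)
        pd.DataFrame({
            "i": edges[:, 0], "j": edges[:, 1],
            "gross": net.gross_flux[edges[:, 0], edges[:, 1]],
            "net": net.net_flux[edges[:, 0], edges[:, 1]],
        }).to_csv(run_dir / "flux_edges.csv", index=False)
        paths = decompose_pathways(net)
        inter_labels = [m for m in config.stepwise_macros if m in labels]
        inter = (np.concatenate([lump.members(labels.index(m)) for m in inter_labels])
                 if inter_labels else np.array([], dtype=int))
        mech = mechanism_fraction(paths, inter)
        pio.write_json(run_dir / "pathways.json", paths)
        pio.write_json(run_dir / "mechanism.json", {
            **mech, "total_flux_per_ns": net.total_flux / model.lag_time,
            "source": A, "sink": B, "intermediates": inter,
        })
    if last < 7:
        return run_dir

    with run.stage("observables"):
        if config.observables and config.source == "four_well":
            obs_dir = run_dir / "observables"
            obs_dir.mkdir(exist_ok=True)
            r_pre = pseudo_particle_positions(landscape.centers[0])[1]
            r_frayed = pseudo_particle_positions(landscape.centers[1])[1]
            spec = TransitionIndexSpec(r_pre=r_pre, r_frayed=r_frayed)
            flat_assign = np.concatenate(dtrajs)
            macro_of_frame = np.full(flat_assign.size, -1, dtype=int)
            valid = remap[flat_assign] >= 0
            macro_of_frame[valid] = lump.crisp_assignment[remap[flat_assign[valid]]]
            rows = []
            offset = 0
            for e in ensembles:
                x = transition_index_series(e, spec)
                t = np.arange(e.n_frames) * e.frame_interval
                rows.append(pd.DataFrame({
                    "frame": np.arange(offset, offset + e.n_frames),
                    "time_ns": t, "observable": "transition_index",
                    "group": spec.probe_group, "value": x,
                }))
                offset += e.n_frames
            ti = pd.concat(rows, ignore_index=True)
            ti["macrostate"] = macro_of_frame
            ti.to_csv(obs_dir / "transition_index.csv", index=False)
            pooled = _pool_ensembles(ensembles)
            for m in range(lump.n_macro):
                frames = np.flatnonzero(macro_of_frame == m)
                if frames.size < 2:
                    continue
                dccm = cross_correlation_map(pooled, list(pooled.groups),
                                             frame_subset=frames)
                dccm.to_csv(obs_dir / f"dccm_{lump.macro_labels[m]}.csv")
            ref = pseudo_particle_positions(landscape.centers[0])
            dist, per_state = distance_to_reference(
                pooled, ref, ["RNA3", "DNA_TN"], average_groups=True,
                state_assignment=macro_of_frame)
            per_state.to_csv(obs_dir / "distance_per_state.csv", index=False)
    if last < 8:
        return run_dir

    with run.stage("report"):
        report_doc = {
            "config_hash": config.config_hash(),
            "n_macrostates": lump.n_macro,
            "macro_labels": lump.macro_labels,
            "populations_pct": (macro_populations(model.stationary, lump) * 100.0),
            "kinetics": pio.read_json(run_dir / "kinetics.json"),
            "mechanism": pio.read_json(run_dir / "mechanism.json"),
            "stage_timings_s": run.timings,
        }
        pio.write_json(run_dir / "report.json", report_doc)
    return run_dir


def _pathway_progress(landscape, points: np.ndarray) -> np.ndarray:
    """Arclength-like progression of points along the well-center polyline.

    For each point, the nearest segment of the polyline through the well
    centers and the clipped projection parameter give a scalar in
    [0, n_wells - 1]; used to order macrostates along the pathway.
    """
    pts = np.atleast_2d(points)
    best = np.full(pts.shape[0], np.inf)
    prog = np.zeros(pts.shape[0])
    for s in range(landscape.n_wells - 1):
        a, b = landscape.centers[s], landscape.centers[s + 1]
        ab = b - a
        t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(pts - proj, axis=1)
        closer = d < best
        best[closer] = d[closer]
        prog[closer] = s + t[closer]
    return prog


def _pool_ensembles(ensembles):
    from .geometry import ConformationEnsemble
    coords = np.concatenate([e.coordinates for e in ensembles])
    rc = None
    if ensembles[0].reaction_coords is not None:
        rc = np.concatenate([e.reaction_coords for e in ensembles])
    return ConformationEnsemble(coords, ensembles[0].labels,
                                frame_interval=ensembles[0].frame_interval,
                                groups=dict(ensembles[0].groups),
                                reaction_coords=rc)


def validate_report(run_dir) -> dict:
    """Automated health checks of a completed run.

    Checks: macrostate populations sum to 100 ± 0.1 %; the slowest implied
    timescale at the chosen lag is within 20% of the next larger candidate
    lag (plateau); residence-probability mismatch below 0.1; net-flux
    conservation at intermediate states below 1e-10 of total flux. Each
    check reports pass/fail with its numbers.
    """
    run_dir = Path(run_dir)
    needed = ["kinetics.json", "implied_timescales.csv", "residence.csv",
              "flux_edges.csv", "mechanism.json", "config.yaml"]
    for name in needed:
        if not (run_dir / name).exists():
            raise IncompleteRunError(f"missing artifact {name} in {run_dir}")
    config = load_config(run_dir / "config.yaml")
    checks = {}

    kin = pio.read_json(run_dir / "kinetics.json")
    total = float(np.sum(kin["population_mean_pct"]))
    checks["population_sum"] = {"pass": abs(total - 100.0) <= 0.1, "value": total}

    its = pd.read_csv(run_dir / "implied_timescales.csv")
    slow = its[its["k"] == 1].set_index("lag")["timescale"]
    larger = [l for l in config.lags if l > config.lag]
    if larger:
        t0, t1 = slow.get(config.lag, np.nan), slow.get(larger[0], np.nan)
        ok = np.isfinite(t0) and np.isfinite(t1) and abs(t1 - t0) <= 0.2 * t0
        checks["timescale_plateau"] = {"pass": bool(ok), "t_at_lag": float(t0),
                                       "t_at_next_lag": float(t1)}
    else:
        checks["timescale_plateau"] = {"pass": True, "note": "no larger candidate lag"}

    res = pd.read_csv(run_dir / "residence.csv")
    worst = float(res["mismatch"].max())
    checks["residence_probability"] = {"pass": worst <= 0.1, "max_mismatch": worst}

    mech = pio.read_json(run_dir / "mechanism.json")
    edges = pd.read_csv(run_dir / "flux_edges.csv")
    n = int(max(edges["i"].max(), edges["j"].max())) + 1
    F = np.zeros((n, n))
    F[edges["i"], edges["j"]] = edges["net"]
    endpoints = set(mech["source"]) | set(mech["sink"])
    inter = [s for s in range(n) if s not in endpoints]
    total_flux = F[list(mech["source"]), :].sum()
    imbalance = max((abs(F[s, :].sum() - F[:, s].sum()) for s in inter), default=0.0)
    checks["flux_conservation"] = {
        "pass": imbalance <= 1e-10 * max(total_flux, 1e-300),
        "max_imbalance": float(imbalance), "total_flux": float(total_flux),
    }
    checks["all_pass"] = {"pass": all(c["pass"] for c in checks.values())}
    return checks
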