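"""Transition path theory: committors, reactive flux, pathway
decomposition and mechanism classification."""

import itertools

import numpy as np
import pytest

from polymsm import (
    committor,
    decompose_pathways,
    mechanism_fraction,
    reactive_flux,
    sample_chain_swarm,
)
from polymsm.errors import InsufficientCoverageError, InvalidSetsError, NoPathError
from polymsm.msm import model_from_matrix
from polymsm.synthetic import GroundTruthChain
from polymsm.tpt import FluxNetwork

from conftest import random_reversible_chain


def _path_chain(n: int) -> np.ndarray:
    """Symmetric birth-death chain on a path graph."""
    T = np.zeros((n, n))
    for i in range(n):
        if i > 0:
            T[i, i - 1] = 0.2
        if i < n - 1:
            T[i, i + 1] = 0.2
        T[i, i] = 1.0 - T[i].sum()
    return T


class TestCommittor:
    def test_three_state_path_symmetry(self):
        q = committor(_path_chain(3), [0], [2])
        assert np.allclose(q, [0.0, 0.5, 1.0])

    def test_gamblers_ruin_four_states(self):
        q = committor(_path_chain(4), [0], [3])
        assert np.allclose(q, [0.0, 1 / 3, 2 / 3, 1.0])

    def test_harmonicity_and_monte_carlo(self, rng):
        T = random_reversible_chain(7, rng)
        A, B = [0], [6]
        q = committor(T, A, B)
        interior = list(range(1, 6))
        assert np.max(np.abs(q[interior] - (T @ q)[interior])) < 1e-12
        # Monte-Carlo hitting probability from state 3
        chain = GroundTruthChain(T)
        trajs = sample_chain_swarm(chain, 2000, 200, starts=np.full(2000, 3), seed=0)
        hits = []
        for t in trajs:
            ia = np.flatnonzero(t == 0)
            ib = np.flatnonzero(t == 6)
            first_a = ia[0] if ia.size else np.inf
            first_b = ib[0] if ib.size else np.inf
            assert min(first_a, first_b) < np.inf
            hits.append(first_b < first_a)
        p = np.mean(hits)
        se = np.sqrt(p * (1 - p) / len(hits))
        assert q[3] == pytest.approx(p, abs=3 * se)

    def test_monotone_along_birth_death_chain(self, rng):
        for n in (4, 6, 9):
            T = _path_chain(n)
            q = committor(T, [0], [n - 1])
            assert np.all(np.diff(q) > 0)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(InvalidSetsError):
            committor(_path_chain(4), [0, 1], [1, 3])


class TestReactiveFlux:
    def test_three_state_hand_computation(self):
        T = np.array([[0.8, 0.2, 0.0], [0.2, 0.6, 0.2], [0.0, 0.2, 0.8]])
        model = model_from_matrix(T)
        net = reactive_flux(model, [0], [2])
        assert np.allclose(model.stationary, 1 / 3)
        assert np.allclose(net.forward_committor, [0.0, 0.5, 1.0])
        assert net.total_flux == pytest.approx(1 / 30)

    def test_no_direct_edge_no_direct_flux(self):
        T = _path_chain(4)
        model = model_from_matrix(T)
        net = reactive_flux(model, [0], [3])
        assert net.gross_flux[0, 3] == 0.0

    def test_kirchhoff_conservation(self, rng):
        T = random_reversible_chain(7, rng)
        model = model_from_matrix(T)
        net = reactive_flux(model, [0, 1], [5, 6])
        for s in (2, 3, 4):
            imbalance = abs(net.net_flux[s].sum() - net.net_flux[:, s].sum())
            assert imbalance < 1e-12 * net.total_flux


def brute_force_decomposition(net: FluxNetwork, max_paths: int = 10_000):
    """Oracle: iterative bottleneck decomposition where the widest path is
    found by exhaustive enumeration of simple paths."""
    cap = net.net_flux.copy()
    cap[:, net.source] = 0.0
    cap[net.sink, :] = 0.0
    n = cap.shape[0]
    out = []
    remaining = net.total_flux
    for _ in range(max_paths):
        if remaining <= 1e-12 * net.total_flux:
            break
        best = None
        # enumerate all simple A->B paths
        def extend(path):
            nonlocal best
            u = path[-1]
            if u in net.sink:
                b = min(cap[path[i], path[i + 1]] for i in range(len(path) - 1))
                if b > 0:
                    key = (-b, len(path), tuple(path))
                    if best is None or key < best[0]:
                        best = (key, list(path), b)
                return
            for v in range(n):
                if cap[u, v] > 0 and v not in path:
                    extend(path + [v])
        for a in net.source:
            extend([a])
        if best is None:
            break
        _, path, b = best
        idx = np.array(path)
        cap[idx[:-1], idx[1:]] -= b
        remaining -= b
        out.append((path, b))
    return out


class TestDecomposePathways:
    def test_single_chain_single_path(self):
        model = model_from_matrix(_path_chain(4))
        net = reactive_flux(model, [0], [3])
        paths = decompose_pathways(net)
        assert len(paths) == 1
        assert paths[0]["path"] == [0, 1, 2, 3]
        assert paths[0]["fraction"] == pytest.approx(1.0)

    def test_two_parallel_paths_ordered_by_capacity(self):
        # hand-built net flux: A=0, B=3, routes via 1 (cap 3) and 2 (cap 1)
        f = np.zeros((4, 4))
        f[0, 1] = f[1, 3] = 3.0
        f[0, 2] = f[2, 3] = 1.0
        net = FluxNetwork(source=np.array([0]), sink=np.array([3]),
                          forward_committor=np.zeros(4), backward_committor=np.zeros(4),
                          gross_flux=f, net_flux=f, total_flux=4.0)
        paths = decompose_pathways(net)
        assert [p["path"] for p in paths] == [[0, 1, 3], [0, 2, 3]]
        assert [p["fraction"] for p in paths] == pytest.approx([0.75, 0.25])

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 8))
            T = random_reversible_chain(n, rng)
            model = model_from_matrix(T)
            net = reactive_flux(model, [0], [n - 1])
            fast = decompose_pathways(net)
            slow = brute_force_decomposition(net)
            assert len(fast) == len(slow)
            for rec, (path, flux) in zip(fast, slow):
                assert rec["path"] == path
                assert rec["flux"] == pytest.approx(flux, abs=1e-10)
            assert sum(p["flux"] for p in fast) == pytest.approx(
                net.total_flux, abs=1e-10)

    def test_invariant_under_state_relabeling(self, rng):
        n = 6
        T = random_reversible_chain(n, rng)
        model = model_from_matrix(T)
        net = reactive_flux(model, [0], [n - 1])
        paths = decompose_pathways(net)
        perm = np.array([0, 3, 1, 4, 2, 5])   # keeps endpoints fixed
        Tp = T[np.ix_(perm, perm)]
        inv = np.argsort(perm)
        netp = reactive_flux(model_from_matrix(Tp),
                             [int(inv[0])], [int(inv[n - 1])])
        pathsp = decompose_pathways(netp)
        mapped = [[int(perm[s]) for s in p["path"]] for p in pathsp]
        assert mapped == [p["path"] for p in paths]
        assert [p["flux"] for p in pathsp] == pytest.approx(
            [p["flux"] for p in paths])

    def test_no_path_rejected(self):
        f = np.zeros((3, 3))
        net = FluxNetwork(source=np.array([0]), sink=np.array([2]),
                          forward_committor=np.zeros(3), backward_committor=np.zeros(3),
                          gross_flux=f, net_flux=f, total_flux=0.0)
        with pytest.raises(NoPathError):
            decompose_pathways(net)


class TestMechanismFraction:
    def test_forced_stepwise_topology(self):
        model = model_from_matrix(_path_chain(4))
        net = reactive_flux(model, [0], [3])
        paths = decompose_pathways(net)
        out = mechanism_fraction(paths, intermediate_states=[1, 2])
        assert out["stepwise"] == pytest.approx(1.0)
        assert out["concerted"] == pytest.approx(0.0)

    def test_single_direct_edge_concerted(self):
        f = np.zeros((2, 2))
        f[0, 1] = 1.0
        net = FluxNetwork(source=np.array([0]), sink=np.array([1]),
                          forward_committor=np.zeros(2), backward_committor=np.zeros(2),
                          gross_flux=f, net_flux=f, total_flux=1.0)
        out = mechanism_fraction(decompose_pathways(net), intermediate_states=[])
        assert out["concerted"] == pytest.approx(1.0)

    def test_weak_direct_channel_fraction(self):
        # chain channel plus a direct edge carrying 1e-6 of the chain capacity
        f = np.zeros((4, 4))
        f[0, 1] = f[1, 2] = f[2, 3] = 1.0
        f[0, 3] = 1e-6
        total = 1.0 + 1e-6
        net = FluxNetwork(source=np.array([0]), sink=np.array([3]),
                          forward_committor=np.zeros(4), backward_committor=np.zeros(4),
                          gross_flux=f, net_flux=f, total_flux=total)
        out = mechanism_fraction(decompose_pathways(net), intermediate_states=[1, 2])
        assert out["stepwise"] >= 0.999

    def test_insufficient_coverage_rejected(self):
        paths = [{"path": [0, 1, 2], "flux": 0.5, "fraction": 0.5,
                  "cumulative_fraction": 0.5}]
        with pytest.raises(InsufficientCoverageError):
            mechanism_fraction(paths, intermediate_states=[1])
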