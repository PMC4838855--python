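"""Generators: landscape construction, Langevin sampler, chain sampler,
correlated-displacement fixture."""

import numpy as np
import pytest

from polymsm import (
    GroundTruthChain,
    LangevinParams,
    MultiWellLandscape,
    build_block_chain,
    build_four_well,
    correlated_displacements,
    sample_chain,
    sample_chain_swarm,
    seed_from_path,
    simulate_langevin,
)
from polymsm.errors import (
    InvalidChainError,
    InvalidCorrelationError,
    InvalidParameterError,
)


class TestBuildFourWell:
    def test_well_minima_at_centers(self, four_well):
        # U at each center ~ -depth (neighbor tails and corridor are small there)
        u = four_well.potential(four_well.centers)
        assert np.allclose(u, -np.array([5.0, 4.0, 4.5, 6.0]), atol=0.05)
        # local minimum within width/10 of each center
        for c, w in zip(four_well.centers, (0.25,) * 4):
            grid = c + np.random.default_rng(0).uniform(-w / 2, w / 2, size=(200, 2))
            best = grid[np.argmin(four_well.potential(grid))]
            assert four_well.potential(c) <= four_well.potential(best) + 1e-2

    def test_deepest_well_is_well_4(self, four_well):
        u = four_well.potential(four_well.centers)
        assert np.argmin(u) == 3

    def test_direct_channel_blocked(self):
        big = build_four_well(direct_barrier=50.0)
        a, b = big.centers[0], big.centers[3]
        seg = a + np.linspace(0.2, 0.8, 31)[:, None] * (b - a)
        minima = big.potential(big.centers[[0, 3]])
        assert np.max(big.potential(seg)) >= minima.max() + 25.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_four_well(spacing=-1.0)
        with pytest.raises(InvalidParameterError):
            build_four_well(widths=(0.2, 0.2, -0.1, 0.2))
        with pytest.raises(InvalidParameterError):
            MultiWellLandscape(np.zeros((1, 2)), [1.0], [1.0])

    def test_gradient_matches_finite_difference(self, four_well):
        rng = np.random.default_rng(7)
        for p in rng.uniform(-1.5, 1.5, size=(20, 2)):
            g = four_well.gradient(p)
            h = 1e-6
            num = np.array([
                (four_well.potential(p + h * e) - four_well.potential(p - h * e)) / (2 * h)
                for e in np.eye(2)
            ])
            assert np.allclose(g, num, atol=1e-4)


class TestSimulateLangevin:
    def test_zero_temperature_at_minimum_is_stationary(self, four_well):
        # refine the minimum first: gradient descent from the center
        p = four_well.centers[3].copy()
        for _ in range(2000):
            p = p - 0.001 * four_well.gradient(p)
        params = LangevinParams(timestep=0.001, n_steps=50, kT=0.0, seed=0)
        ens = simulate_langevin(four_well, params, p)
        assert np.allclose(ens.reaction_coords, p, atol=1e-8)

    def test_zero_temperature_energy_nonincreasing(self, four_well):
        params = LangevinParams(timestep=0.001, n_steps=500, kT=0.0, seed=0)
        start = four_well.centers[0] + np.array([0.2, 0.1])
        ens = simulate_langevin(four_well, params, start)
        u = four_well.potential(ens.reaction_coords)
        assert np.all(np.diff(u) <= 1e-10)

    def test_bitwise_reproducible(self, four_well):
        params = LangevinParams(timestep=0.002, n_steps=300, kT=0.8, seed=42)
        a = simulate_langevin(four_well, params, four_well.centers[0])
        b = simulate_langevin(four_well, params, four_well.centers[0])
        assert np.array_equal(a.coordinates, b.coordinates)
        assert np.array_equal(a.reaction_coords, b.reaction_coords)

    def test_save_stride_frame_count(self, four_well):
        params = LangevinParams(timestep=0.002, n_steps=100, save_stride=10, seed=0)
        ens = simulate_langevin(four_well, params, four_well.centers[0])
        assert ens.n_frames == 11
        assert ens.frame_interval == pytest.approx(0.02)

    def test_symmetric_two_well_boltzmann_symmetry(self):
        # long run in a symmetric double well: half the frames in each basin
        two = MultiWellLandscape(
            centers=[[-0.5, 0.0], [0.5, 0.0]], depths=[4.0, 4.0], widths=[0.25, 0.25],
            confine_center=[0.0, 0.0], confine_radius=0.8, confine_strength=100.0,
        )
        params = LangevinParams(timestep=0.002, n_steps=200_000, kT=1.0, seed=11)
        ens = simulate_langevin(two, params, np.array([-0.5, 0.0]))
        frac_right = np.mean(ens.reaction_coords[:, 0] > 0)
        assert frac_right == pytest.approx(0.5, abs=0.05)

    def test_single_well_variance_matches_harmonic(self):
        # near the minimum U ~ (depth/width^2) |p|^2 / 2 per coordinate,
        # so each coordinate's variance should approach kT width^2 / depth
        # deep well so the quartic (anharmonic) correction stays small
        one = MultiWellLandscape(
            centers=[[0.0, 0.0], [10.0, 0.0]], depths=[40.0, 1e-9], widths=[0.3, 0.1],
        )
        params = LangevinParams(timestep=1e-4, n_steps=100_000, kT=1.0, seed=5)
        ens = simulate_langevin(one, params, np.array([0.0, 0.0]))
        expected = 1.0 * 0.3**2 / 40.0
        var = ens.reaction_coords.var(axis=0)
        assert np.allclose(var, expected, rtol=0.10)


class TestSeedFromPath:
    def test_two_interpolants_are_the_endpoints(self, four_well):
        params = LangevinParams(timestep=0.002, n_steps=5, kT=0.0, seed=0)
        ends = [four_well.centers[0], four_well.centers[1]]
        swarm = seed_from_path(four_well, ends, 2, params)
        assert np.allclose(swarm[0].reaction_coords[0], ends[0])
        assert np.allclose(swarm[1].reaction_coords[0], ends[1])

    def test_five_interpolants_linear_spacing(self, four_well):
        params = LangevinParams(timestep=0.002, n_steps=1, kT=0.0, seed=0)
        ends = [np.array([0.0, 0.0]), np.array([1.0, 0.0])]
        swarm = seed_from_path(four_well, ends, 5, params)
        starts = np.array([e.reaction_coords[0] for e in swarm])
        assert np.allclose(starts[:, 0], [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_swarm_visits_both_endpoint_basins(self, four_well):
        params = LangevinParams(timestep=0.002, n_steps=400, kT=0.8, seed=3)
        ends = [four_well.centers[0], four_well.centers[1]]
        swarm = seed_from_path(four_well, ends, 40, params)
        basins = set()
        for e in swarm:
            basins.update(four_well.basin_labels(e.reaction_coords).tolist())
        assert {0, 1} <= basins


class TestSampleChain:
    def test_identity_matrix_constant(self):
        chain = GroundTruthChain(np.eye(4))
        traj = sample_chain(chain, 50, start=2, seed=0)
        assert np.all(traj == 2)

    def test_alternating_two_state(self):
        chain = GroundTruthChain(np.array([[0.0, 1.0], [1.0, 0.0]]))
        traj = sample_chain(chain, 9, start=0, seed=3)
        assert np.array_equal(traj, np.arange(10) % 2)

    def test_empirical_transition_frequency(self, two_state_chain):
        traj = sample_chain(two_state_chain, 100_000, start=0, seed=7)
        at0 = traj[:-1] == 0
        frac = np.mean(traj[1:][at0] == 1)
        assert frac == pytest.approx(0.1, abs=0.01)

    def test_row_sum_violation_rejected(self):
        with pytest.raises(InvalidChainError):
            GroundTruthChain(np.array([[0.9, 0.2], [0.1, 0.9]]))

    def test_swarm_matches_seeded_rows(self, block_chain):
        trajs = sample_chain_swarm(block_chain, 40, 500, seed=9)
        assert len(trajs) == 40 and all(len(t) == 501 for t in trajs)
        again = sample_chain_swarm(block_chain, 40, 500, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(trajs, again))

    def test_empirical_rows_converge(self, block_chain):
        # pooled empirical transition frequencies approach ground truth rows
        trajs = sample_chain_swarm(block_chain, 50, 2000, seed=2)
        n = block_chain.n_states
        counts = np.zeros((n, n))
        for t in trajs:
            np.add.at(counts, (t[:-1], t[1:]), 1.0)
        visits = counts.sum(axis=1)
        emp = counts / visits[:, None]
        err = np.abs(emp - block_chain.transition_matrix).sum(axis=1)
        assert np.all(err < 5.0 / np.sqrt(visits))


class TestCorrelatedDisplacements:
    def test_identity_correlation_independent(self):
        ens = correlated_displacements(np.eye(4), n_frames=4000, seed=0)
        from polymsm import cross_correlation_map
        c = cross_correlation_map(ens, ens.labels).to_numpy()
        off = c[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 3.0 / np.sqrt(4000))

    def test_duplicated_particle_perfectly_correlated(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        ens = correlated_displacements(C, n_frames=500, seed=1)
        from polymsm import cross_correlation_map
        c = cross_correlation_map(ens, ens.labels).to_numpy()
        assert c[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_target_correlation_recovered(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.8
        ens = correlated_displacements(C, n_frames=10_000, seed=2)
        from polymsm import cross_correlation_map
        c = cross_correlation_map(ens, ens.labels).to_numpy()
        assert c[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_non_psd_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(InvalidCorrelationError):
            correlated_displacements(C, n_frames=10)


def test_block_chain_is_reversible_with_blockwise_stationary(block_chain):
    T = block_chain.transition_matrix
    pi = block_chain.stationary()
    flux = pi[:, None] * T
    assert np.max(np.abs(flux - flux.T)) < 1e-12
    pops = np.array([pi[block_chain.state_labels == b].sum() for b in range(4)])
    # strengths are proportional to the emulated macrostate populations
    assert np.argmax(pops) == 3 and np.argmin(pops) == 2
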