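"""Geometric observables: Kabsch RMSD, RMSF, transition index,
destination classification, DCCM, distance-to-reference."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from polymsm import (
    ConformationEnsemble,
    TransitionIndexSpec,
    classify_ts_ensemble,
    correlated_displacements,
    cross_correlation_map,
    distance_to_reference,
    kabsch_rmsd,
    rmsf,
    transition_index,
    transition_index_series,
)
from polymsm.errors import (
    AlignmentDegenerateError,
    DegenerateReferenceError,
    EmptyInputError,
    InsufficientFramesError,
    UnknownSelectionError,
    ZeroVarianceError,
)


def _random_frame(rng, n=8):
    return rng.normal(size=(n, 3))


class TestKabschRmsd:
    def test_identical_frames_zero(self, rng):
        f = _random_frame(rng)
        assert kabsch_rmsd(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, rng):
        f = _random_frame(rng)
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(f) + np.array([1.0, -2.0, 3.0])
        assert kabsch_rmsd(f, moved, fit=True) == pytest.approx(0.0, abs=1e-10)

    def test_two_point_raw_rmsd(self):
        # two particles at distance 1 vs 3, centroids aligned, no rotation fit
        a = np.array([[-0.5, 0, 0], [0.5, 0, 0]])
        b = np.array([[-1.5, 0, 0], [1.5, 0, 0]])
        assert kabsch_rmsd(a, b, fit=False) == pytest.approx(1.0)

    def test_symmetry_and_common_rigid_invariance(self, rng):
        a, b = _random_frame(rng), _random_frame(rng)
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-10)
        rot = Rotation.random(rng=12)
        shift = np.array([0.3, 0.7, -1.1])
        assert kabsch_rmsd(rot.apply(a) + shift, rot.apply(b) + shift) == pytest.approx(
            kabsch_rmsd(a, b), abs=1e-10
        )

    def test_collinear_group_rejected(self):
        line = np.stack([np.linspace(0, 1, 5), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(AlignmentDegenerateError):
            kabsch_rmsd(line, line + 1.0, fit=True)


class TestRmsf:
    def test_constant_ensemble_all_zero(self, rng):
        frame = _random_frame(rng, 5)
        ens = ConformationEnsemble(np.repeat(frame[None], 10, axis=0),
                                   labels=list("abcde"))
        assert np.allclose(rmsf(ens), 0.0, atol=1e-12)

    def test_single_oscillating_particle(self):
        a = 0.7
        coords = np.zeros((2, 3, 3))
        coords[:, 1, :] = [[1, 2, 3], [1, 2, 3]]
        coords[:, 2, :] = [[4, 5, 6], [4, 5, 6]]
        coords[0, 0, 0] = +a
        coords[1, 0, 0] = -a
        ens = ConformationEnsemble(coords, labels=["m", "f1", "f2"])
        out = rmsf(ens, align=False)
        assert out[0] == pytest.approx(a)
        assert np.allclose(out[1:], 0.0, atol=1e-12)

    def test_unit_variance_gaussian_rmsf_sqrt3(self):
        ens = correlated_displacements(np.eye(3), n_frames=8000, seed=4)
        out = rmsf(ens, align=False)
        assert np.allclose(out, np.sqrt(3.0), rtol=0.05)

    def test_single_frame_rejected(self, rng):
        ens = ConformationEnsemble(_random_frame(rng)[None], labels=[str(i) for i in range(8)])
        with pytest.raises(InsufficientFramesError):
            rmsf(ens)


class TestTransitionIndex:
    spec = TransitionIndexSpec(r_pre=np.array([1.0, 0.0, 0.0]),
                               r_frayed=np.array([3.0, 2.0, 0.0]))

    def test_endpoints(self):
        assert transition_index(self.spec.r_pre, self.spec) == 0.0
        assert transition_index(self.spec.r_frayed, self.spec) == 1.0

    def test_midpoint_is_half(self):
        mid = (self.spec.r_pre + self.spec.r_frayed) / 2
        assert transition_index(mid, self.spec) == pytest.approx(0.5)

    def test_rigid_motion_equivariance(self, rng):
        rot = Rotation.random(rng=3)
        shift = np.array([1.0, -0.5, 2.0])
        point = rng.normal(size=3)
        moved_spec = TransitionIndexSpec(rot.apply(self.spec.r_pre) + shift,
                                         rot.apply(self.spec.r_frayed) + shift)
        assert transition_index(rot.apply(point) + shift, moved_spec) == pytest.approx(
            transition_index(point, self.spec), abs=1e-10
        )

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            TransitionIndexSpec(np.zeros(3), np.zeros(3))

    def test_series_uses_probe_group_com(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 0, 0] = [1.0, 2.0, 3.0]   # DNA_TN-like probe
        coords[:, 1, 0] = 99.0              # other particle, ignored
        ens = ConformationEnsemble(coords, labels=["DNA_TN", "other"])
        spec = TransitionIndexSpec(np.array([1.0, 0, 0]), np.array([3.0, 0, 0]))
        assert np.allclose(transition_index_series(ens, spec), [0.0, 0.5, 1.0])


class TestClassifyTsEnsemble:
    def test_direct_count(self):
        out = classify_ts_ensemble([0.1, 0.9, 0.2, 0.4], threshold=0.5)
        assert out["pre_like"] == pytest.approx(0.75)
        assert out["pre_like"] + out["frayed_like"] == pytest.approx(1.0)

    def test_all_zero_pre_like(self):
        assert classify_ts_ensemble([0.0] * 5)["pre_like"] == 1.0

    def test_uniform_half(self):
        x = np.random.default_rng(0).uniform(size=10_000)
        assert classify_ts_ensemble(x)["pre_like"] == pytest.approx(0.5, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            classify_ts_ensemble([])


class TestCrossCorrelationMap:
    def test_self_pair_unity_and_symmetry(self):
        ens = correlated_displacements(np.eye(3), n_frames=200, seed=0)
        c = cross_correlation_map(ens, ens.labels).to_numpy()
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c, c.T, atol=1e-12)
        assert np.all(np.abs(c) <= 1.0 + 1e-12)

    def test_anticorrelated_pair(self):
        coords = np.zeros((100, 2, 3))
        x = np.random.default_rng(1).normal(size=100)
        coords[:, 0, 0] = x
        coords[:, 1, 0] = -x
        ens = ConformationEnsemble(coords, labels=["a", "b"])
        c = cross_correlation_map(ens, ["a", "b"]).to_numpy()
        assert c[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_group_named(self):
        coords = np.zeros((50, 2, 3))
        coords[:, 0, 0] = np.random.default_rng(0).normal(size=50)
        ens = ConformationEnsemble(coords, labels=["moving", "frozen"])
        with pytest.raises(ZeroVarianceError, match="frozen"):
            cross_correlation_map(ens, ["moving", "frozen"])


class TestDistanceToReference:
    def test_identical_reference_zero(self, rng):
        frame = _random_frame(rng, 4)
        ens = ConformationEnsemble(np.repeat(frame[None], 6, axis=0),
                                   labels=list("wxyz"))
        d = distance_to_reference(ens, frame, ["w", "x"])
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_three_four_five(self, rng):
        frame = _random_frame(rng, 2)
        moved = frame.copy()
        moved[0] += np.array([3.0, 4.0, 0.0])
        ens = ConformationEnsemble(np.repeat(moved[None], 3, axis=0), labels=["a", "b"])
        d = distance_to_reference(ens, frame, ["a"])
        assert np.allclose(d, 5.0)

    def test_group_average(self, rng):
        frame = _random_frame(rng, 2)
        moved = frame.copy()
        moved[0, 0] += 2.0
        moved[1, 0] += 4.0
        ens = ConformationEnsemble(np.repeat(moved[None], 3, axis=0), labels=["a", "b"])
        d = distance_to_reference(ens, frame, ["a", "b"], average_groups=True)
        assert np.allclose(d, 3.0)

    def test_per_state_summary(self, rng):
        frame = _random_frame(rng, 2)
        moved = frame + np.array([1.0, 0, 0])
        coords = np.concatenate([np.repeat(frame[None], 4, 0), np.repeat(moved[None], 4, 0)])
        ens = ConformationEnsemble(coords, labels=["a", "b"])
        _, table = distance_to_reference(ens, frame, ["a"], average_groups=True,
                                         state_assignment=[0, 0, 0, 0, 1, 1, 1, 1])
        assert np.allclose(table["mean"], [0.0, 1.0])
        assert np.allclose(table["sd"], 0.0)

    def test_missing_group_rejected(self, rng):
        frame = _random_frame(rng, 2)
        ens = ConformationEnsemble(frame[None], labels=["a", "b"])
        with pytest.raises(UnknownSelectionError):
            distance_to_reference(ens, frame, ["nope"])
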