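"""Rigid-body superposition and RMSF analysis."""

import numpy as np
import pytest

from trpkin.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    InvalidInputError,
)
from trpkin.structure import Trajectory, delta_rmsf, rmsf, superpose
from trpkin.synthetic import TrajectorySpec, gen_trajectory


def quaternion_rmsd(mobile, reference):
    """Independent superposition oracle: Horn's quaternion eigenvalue method."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    M = a.T @ b
    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    K = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(a**2) + np.sum(b**2) - 2.0 * lam_max) / len(a)
    return np.sqrt(max(msd, 0.0))


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = superpose(pts, pts)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0.0, atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pts @ Rz.T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(moved @ R.T + t, pts, atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_rmsd_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        _, _, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-10)

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert superpose(a, b)[2] == pytest.approx(superpose(b, a)[2], abs=1e-10)

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(InvalidInputError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        traj, _ = gen_trajectory(
            TrajectorySpec(baseline_amp_A=0.0, n_frames=20, seed=0, global_motion=True)
        )
        prof = rmsf(traj)
        assert np.allclose(prof.rmsf_A, 0.0, atol=1e-8)

    def test_single_oscillating_atom(self):
        """200 static anchors + 1 atom alternating +/-delta recovers delta."""
        rng = np.random.default_rng(2)
        scaffold = rng.normal(scale=10.0, size=(201, 3))
        delta = 0.7
        frames = np.repeat(scaffold[None], 40, axis=0)
        frames[::2, -1, 0] += delta
        frames[1::2, -1, 0] -= delta
        traj = Trajectory(coords=frames, residue_ids=np.arange(1, 202))
        prof = rmsf(traj)
        assert prof.rmsf_A[-1] == pytest.approx(delta, rel=0.01)
        assert np.all(prof.rmsf_A[:-1] < 0.02 * delta)

    def test_isotropic_jitter_converges_to_sd_sqrt3(self):
        """Per-axis sd s gives RMSF -> s*sqrt(3) at many frames."""
        s = 0.5 / np.sqrt(3.0)
        # enough atoms that the 6 rigid-body DOF absorb <<2% of the variance
        traj, truth = gen_trajectory(
            TrajectorySpec(
                n_residues=300, n_frames=10_000, baseline_amp_A=0.5, seed=5,
                global_motion=False,
            )
        )
        prof = rmsf(traj)
        assert np.mean(prof.rmsf_A) == pytest.approx(s * np.sqrt(3.0), rel=0.02)

    def test_invariant_under_global_motion(self):
        spec = dict(n_residues=32, n_frames=150, baseline_amp_A=0.4, seed=9)
        fixed, _ = gen_trajectory(TrajectorySpec(**spec, global_motion=False))
        moved = fixed.coords.copy()
        rng = np.random.default_rng(11)
        for i in range(len(moved)):
            moved[i] = moved[i] @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
        prof_fixed = rmsf(fixed)
        prof_moved = rmsf(Trajectory(coords=moved, residue_ids=fixed.residue_ids))
        assert np.allclose(prof_fixed.rmsf_A, prof_moved.rmsf_A, atol=1e-8)

    def test_reference_policies_recorded(self):
        traj, _ = gen_trajectory(TrajectorySpec(n_frames=30, seed=1))
        assert rmsf(traj).reference_policy == "mean_structure"
        assert rmsf(traj, "first_frame").reference_policy == "first_frame"
        # deviations from frame 1 exceed deviations from the mean
        assert np.all(
            rmsf(traj, "first_frame").rmsf_A >= rmsf(traj).rmsf_A - 1e-12
        )

    def test_single_frame_rejected(self):
        traj = Trajectory(coords=np.zeros((1, 5, 3)), residue_ids=np.arange(5))
        with pytest.raises(InsufficientDataError):
            rmsf(traj)


class TestDeltaRMSF:
    def test_identical_profiles_cancel(self):
        traj, _ = gen_trajectory(TrajectorySpec(n_frames=50, seed=3))
        prof = rmsf(traj)
        assert np.all(delta_rmsf(prof, prof).rmsf_A == 0.0)

    def test_antisymmetry(self):
        a = rmsf(gen_trajectory(TrajectorySpec(n_frames=50, seed=3))[0])
        b = rmsf(gen_trajectory(TrajectorySpec(n_frames=50, seed=4))[0])
        assert np.allclose(
            delta_rmsf(a, b).rmsf_A, -delta_rmsf(b, a).rmsf_A, atol=1e-15
        )

    def test_sign_localizes_to_flexible_loop(self):
        """Doubled loop amplitudes give positive differences exactly there."""
        loops = tuple(range(20, 29))
        flexible, _ = gen_trajectory(
            TrajectorySpec(
                n_frames=800, seed=6, loop_residues=loops, loop_amp_A=1.5,
                global_motion=False,
            )
        )
        rigid, _ = gen_trajectory(
            TrajectorySpec(n_frames=800, seed=7, global_motion=False)
        )
        diff = delta_rmsf(rmsf(flexible), rmsf(rigid))
        loop_mask = np.isin(diff.residue_ids, loops)
        assert np.all(diff.rmsf_A[loop_mask] > 0.5)
        assert np.all(np.abs(diff.rmsf_A[~loop_mask]) < 0.2)

    def test_mismatched_residues_rejected(self):
        a = rmsf(gen_trajectory(TrajectorySpec(n_frames=20, seed=1))[0])
        b = rmsf(gen_trajectory(TrajectorySpec(n_residues=32, n_frames=20, seed=1))[0])
        with pytest.raises(InvalidInputError):
            delta_rmsf(a, b)
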