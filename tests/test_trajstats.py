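import numpy as np
import pytest

import condiv as cv
from condiv.trajstats import (HBondSpec, Trajectory, cross_correlation,
                              hbond_occupancy, kabsch_superpose,
                              read_trajectory_pdb, read_trajectory_xyz,
                              rmsd_series, rmsf)


def _random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _traj(coords, resnums=None):
    coords = np.asarray(coords, dtype=float)
    a = coords.shape[1]
    return Trajectory(
        coords=coords,
        chains=np.asarray(["A"] * a),
        resnums=np.asarray(resnums if resnums is not None else np.arange(1, a + 1)),
        resnames=np.asarray(["GLY"] * a),
        atom_names=np.asarray(["CA"] * a),
    )


class TestKabsch:
    def test_rigid_copy_recovered_exactly(self, rng):
        ref = rng.normal(size=(20, 3))
        rot = _random_rotation(rng)
        mobile = ref @ rot.T + np.array([1.0, -2.0, 3.0])
        r, t, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd <= 1e-10
        assert np.allclose(mobile @ r.T + t, ref, atol=1e-9)

    def test_identical_inputs_identity_transform(self, rng):
        ref = rng.normal(size=(5, 3))
        r, t, rmsd = kabsch_superpose(ref, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(r, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0.0, atol=1e-10)

    def test_mirror_image_not_reflected_away(self):
        # chiral 4-point set; its mirror cannot be superposed by a rotation
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mirror = ref * np.array([1, 1, -1])
        rot, _, rmsd = kabsch_superpose(mirror, ref)
        assert rmsd > 0.1
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self, rng):
        frame = rng.normal(size=(10, 3))
        traj = _traj(np.repeat(frame[None], 5, axis=0))
        assert rmsd_series(traj).max() <= 1e-10

    def test_rigidly_transformed_frame_scores_zero(self, rng):
        frame = rng.normal(size=(10, 3))
        rot = _random_rotation(rng)
        coords = np.stack([frame, frame @ rot.T + 4.0])
        traj = _traj(coords)
        assert rmsd_series(traj)[1] <= 1e-10

    def test_single_displaced_atom_formula(self, rng):
        # n selected atoms, one displaced by d on a large rigid scaffold:
        # rmsd ~= d / sqrt(n) (the scaffold pins the superposition)
        n, d = 400, 2.0
        frame = rng.normal(scale=20.0, size=(n, 3))
        frame2 = frame.copy()
        frame2[0, 0] += d
        traj = _traj(np.stack([frame, frame2]))
        expected = d / np.sqrt(n)
        assert rmsd_series(traj)[1] == pytest.approx(expected, rel=0.02)

    def test_empty_selection_rejected(self, rng):
        traj = _traj(rng.normal(size=(2, 5, 3)))
        with pytest.raises(ValueError):
            rmsd_series(traj, selection=np.array([], dtype=int))


class TestRmsf:
    def test_two_frame_symmetric_displacement(self, rng):
        # atom at +d and -d along x with a large fixed scaffold: rmsf = d
        n, d = 200, 1.5
        scaffold = rng.normal(scale=15.0, size=(n, 3))
        f1, f2 = scaffold.copy(), scaffold.copy()
        f1[0, 0] += d
        f2[0, 0] -= d
        traj = _traj(np.stack([f1, f2]))
        values = rmsf(traj)
        assert values[0] == pytest.approx(d, rel=0.02)

    def test_static_trajectory_zero(self, rng):
        frame = rng.normal(size=(8, 3))
        traj = _traj(np.repeat(frame[None], 4, axis=0))
        assert rmsf(traj).max() <= 1e-10

    def test_single_frame_rejected(self, rng):
        traj = _traj(rng.normal(size=(1, 5, 3)))
        with pytest.raises(ValueError):
            rmsf(traj)

    def test_rigid_motion_of_whole_system_removed(self):
        spec = cv.SyntheticTrajSpec(n_atoms=80, n_frames=400,
                                    sigmas=np.full(80, 0.3), seed=21)
        plain, _ = cv.gen_trajectory(spec)
        spec_moved = cv.SyntheticTrajSpec(n_atoms=80, n_frames=400,
                                          sigmas=np.full(80, 0.3), seed=21,
                                          rigid_motion=True)
        moved, _ = cv.gen_trajectory(spec_moved)
        assert np.abs(rmsf(plain) - rmsf(moved)).max() <= 1e-8


class TestCrossCorrelation:
    def test_diagonal_exactly_one(self, rng):
        traj = _traj(rng.normal(size=(50, 6, 3)))
        C = cross_correlation(traj)
        assert np.allclose(np.diag(C), 1.0)

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(5)
        scaffold = rng.normal(scale=25.0, size=(100, 3))
        frames = []
        for t in range(60):
            f = scaffold.copy()
            v = rng.normal(size=3)
            f[0] += v
            f[1] -= v
            frames.append(f)
        traj = _traj(np.asarray(frames))
        C = cross_correlation(traj, superpose=False)
        assert C[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_symmetry_and_zero_variance_handling(self, rng):
        coords = rng.normal(size=(30, 5, 3))
        coords[:, 2] = 0.0                     # frozen atom
        traj = _traj(coords)
        C = cross_correlation(traj, superpose=False)
        assert np.max(np.abs(C - C.T)) <= 1e-12
        assert C[2, 2] == 1.0
        assert np.abs(C[2, [0, 1, 3, 4]]).max() == 0.0

    def test_underlying_covariance_positive_semidefinite(self, rng):
        traj = _traj(rng.normal(size=(100, 8, 3)))
        sub = traj.coords - traj.coords.mean(axis=0)
        cov = np.einsum("fik,fjk->ij", sub, sub) / sub.shape[0]
        assert np.linalg.eigvalsh(cov).min() >= -1e-10


class TestHbondOccupancy:
    def _toggled_traj(self, dists, antecedent=True):
        frames = []
        for d in dists:
            frame = [[-1.5, 0, 0], [0, 0, 0], [d, 0, 0]]
            frames.append(frame)
        coords = np.asarray(frames, dtype=float)
        return Trajectory(
            coords=coords,
            chains=np.asarray(["A", "A", "A"]),
            resnums=np.asarray([1, 1, 2]),
            resnames=np.asarray(["SER", "SER", "GLY"]),
            atom_names=np.asarray(["CB", "OG", "O"]),
        )

    def test_counting_is_exact(self):
        traj = self._toggled_traj([3.0] * 9 + [4.0])
        spec = HBondSpec(donor=("A", 1, "OG"), acceptor=("A", 2, "O"),
                         antecedent=("A", 1, "CB"), dist_cutoff=3.5,
                         angle_cutoff=120.0)
        assert hbond_occupancy(traj, spec) == pytest.approx(0.9, abs=1e-15)

    def test_all_frames_satisfied(self):
        traj = self._toggled_traj([3.0, 3.2, 2.8])
        spec = HBondSpec(donor=("A", 1, "OG"), acceptor=("A", 2, "O"),
                         antecedent=("A", 1, "CB"))
        assert hbond_occupancy(traj, spec) == 1.0

    def test_angle_criterion_applies(self):
        # acceptor placed on the same side as the antecedent: angle ~ 0
        coords = np.asarray([[[-1.5, 0, 0], [0, 0, 0], [-3.0, 0, 0]]])
        coords = np.repeat(coords, 2, axis=0)
        traj = Trajectory(coords=coords,
                          chains=np.asarray(["A", "A", "A"]),
                          resnums=np.asarray([1, 1, 2]),
                          resnames=np.asarray(["SER", "SER", "GLY"]),
                          atom_names=np.asarray(["CB", "OG", "O"]))
        spec = HBondSpec(donor=("A", 1, "OG"), acceptor=("A", 2, "O"),
                         antecedent=("A", 1, "CB"), dist_cutoff=3.5,
                         angle_cutoff=120.0)
        assert hbond_occupancy(traj, spec) == 0.0
        relaxed = HBondSpec(donor=("A", 1, "OG"), acceptor=("A", 2, "O"),
                            dist_cutoff=3.5, angle_cutoff=None)
        assert hbond_occupancy(traj, relaxed) == 1.0

    def test_missing_atom_named_in_error(self):
        traj = self._toggled_traj([3.0])
        spec = HBondSpec(donor=("A", 1, "NZ"), acceptor=("A", 2, "O"),
                         angle_cutoff=None)
        with pytest.raises(KeyError, match="NZ"):
            hbond_occupancy(traj, spec)


class TestTrajectoryIO:
    def test_multi_model_pdb_reader(self, tmp_path):
        path = tmp_path / "t.pdb"
        lines = []
        for m, x in ((1, 0.0), (2, 1.0)):
            lines.append(f"MODEL     {m:4d}\n")
            lines.append(f"ATOM      1  CA  GLY A   1    {x:8.3f}{0.0:8.3f}{0.0:8.3f}"
                         f"  1.00  0.00           C\n")
            lines.append("ENDMDL\n")
        path.write_text("".join(lines) + "END\n")
        traj = read_trajectory_pdb(str(path))
        assert traj.n_frames == 2 and traj.n_atoms == 1
        assert traj.coords[1, 0, 0] == pytest.approx(1.0)

    def test_xyz_table_reader(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text("0 0 0\n1 0 0\n\n0 0 1\n1 0 1\n")
        traj = read_trajectory_xyz(str(path))
        assert traj.n_frames == 2 and traj.n_atoms == 2
        assert traj.coords[1, 0, 2] == pytest.approx(1.0)

    def test_selection_and_exclusion(self, rng):
        coords = rng.normal(size=(3, 4, 3))
        traj = Trajectory(coords=coords,
                          chains=np.asarray(["A", "A", "B", "A"]),
                          resnums=np.asarray([1, 2, 3, 4]),
                          resnames=np.asarray(["GLY"] * 4),
                          atom_names=np.asarray(["CA", "CB", "CA", "CA"]))
        assert list(traj.select("name CA")) == [0, 2, 3]
        assert list(traj.select("name CA and chain A")) == [0, 3]
        assert list(traj.select("name CA", exclude_residues=[(3, 4)])) == [0]
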