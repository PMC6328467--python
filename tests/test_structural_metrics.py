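"""Superposition, RMSD statistics, B-factors and radius of gyration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gsecdyn as g
from gsecdyn.core_io import AtomSelection, Trajectory
from gsecdyn.structural_metrics import B_PREFACTOR


def quaternion_rmsd_oracle(mobile, reference):
    """Independent optimal-superposition RMSD via the quaternion
    (Horn) eigenvalue method."""
    x = mobile - mobile.mean(0)
    y = reference - reference.mean(0)
    M = x.T @ y
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    n = len(mobile)
    msd = max((np.sum(x**2) + np.sum(y**2) - 2 * lam) / n, 0.0)
    return np.sqrt(msd)


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        tr, rmsd = g.superpose(pts, pts)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-10)
        assert rmsd < 1e-10

    def test_recovers_exact_rigid_motion(self, rng):
        pts = rng.normal(size=(8, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        moved = pts @ R.T + [1.0, -2.0, 0.5]
        tr, rmsd = g.superpose(moved, pts)
        assert rmsd < 1e-10
        np.testing.assert_allclose(tr.apply(moved), pts, atol=1e-9)

    def test_matches_quaternion_oracle_with_noise(self, rng):
        for _ in range(10):
            ref = rng.normal(size=(5, 3))
            R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
            mobile = ref @ R.T + rng.normal(0, 0.1, size=(5, 3))
            _, rmsd = g.superpose(mobile, ref)
            assert abs(rmsd - quaternion_rmsd_oracle(mobile, ref)) < 1e-6

    def test_invariant_under_rigid_premotion(self, rng):
        ref = rng.normal(size=(20, 3))
        mobile = ref + rng.normal(0, 0.3, size=(20, 3))
        _, rmsd0 = g.superpose(mobile, ref)
        R = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        _, rmsd1 = g.superpose(mobile @ R.T + [3, 4, 5], ref)
        assert abs(rmsd0 - rmsd1) < 1e-8

    def test_too_few_atoms_and_zero_weights(self, rng):
        pts = rng.normal(size=(2, 3))
        with pytest.raises(ValueError):
            g.superpose(pts, pts)
        pts = rng.normal(size=(4, 3))
        with pytest.raises(ValueError):
            g.superpose(pts, pts, weights=np.zeros(4))


class TestAlignTrajectory:
    def test_rigid_tumble_collapses_to_reference(self, rng):
        base = rng.normal(size=(12, 3))
        frames = []
        for k in range(6):
            R = Rotation.random(random_state=np.random.RandomState(k)).as_matrix()
            frames.append(base @ R.T + rng.normal(size=3))
        traj = Trajectory(np.stack(frames))
        sel = AtomSelection(np.arange(12))
        aligned = g.align_trajectory(traj, sel, 0)
        for f in range(6):
            np.testing.assert_allclose(aligned.coordinates[f], aligned.coordinates[0],
                                       atol=1e-8)

    def test_idempotent(self, rng):
        traj = Trajectory(rng.normal(size=(4, 10, 3)))
        sel = AtomSelection(np.arange(10))
        once = g.align_trajectory(traj, sel, 0)
        twice = g.align_trajectory(once, sel, 0)
        np.testing.assert_allclose(once.coordinates, twice.coordinates, atol=1e-10)

    def test_transform_applies_to_all_atoms(self, rng):
        """A rigid protein plus a lipid drifting relative to it: after
        alignment on the protein the lipid displacement is preserved in the
        protein frame."""
        protein = rng.normal(size=(10, 3))
        lipid0 = np.array([[8.0, 0.0, 0.0]])
        drift = np.array([0.1, 0.0, 0.0])
        frames = []
        for k in range(5):
            R = Rotation.from_euler("z", 10 * k, degrees=True).as_matrix()
            prot = protein @ R.T
            lip = (lipid0 + k * drift) @ R.T
            frames.append(np.vstack([prot, lip]))
        traj = Trajectory(np.stack(frames))
        aligned = g.align_trajectory(traj, AtomSelection(np.arange(10)), 0)
        for k in range(5):
            np.testing.assert_allclose(aligned.coordinates[k][:10], protein, atol=1e-8)
            np.testing.assert_allclose(aligned.coordinates[k][10], lipid0[0] + k * drift,
                                       atol=1e-8)


class TestRmsdSeries:
    def test_reference_frame_is_zero(self, rng):
        traj = Trajectory(rng.normal(size=(3, 8, 3)))
        sel = AtomSelection(np.arange(8))
        series = g.rmsd_series(traj, sel, sel, reference=1)
        assert series.values[1] < 1e-10

    def test_single_displaced_atom_hand_value(self):
        """One of four measured atoms displaced by 2 Å with a rigid fit
        elsewhere: RMSD = sqrt(2^2/4) = 1.0 Å."""
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4],
                         [10, 10, 10], [14, 10, 10], [10, 14, 10], [10, 10, 14]],
                        dtype=float)
        frame2 = base.copy()
        frame2[3, 2] += 2.0       # displace one measured atom
        traj = Trajectory(np.stack([base, frame2]))
        fit = AtomSelection(np.arange(4, 8))     # rigid sub-structure
        measure = AtomSelection(np.arange(0, 4))
        series = g.rmsd_series(traj, fit, measure, reference=0)
        np.testing.assert_allclose(series.values, [0.0, 1.0], atol=1e-10)

    def test_gaussian_fluctuations_match_closed_form(self, rng):
        """Isotropic jitter sigma per coordinate about a rigid frame has
        E[RMSD^2] = 3 sigma^2; the fit is on separate rigid atoms."""
        sigma = 0.3
        rigid = rng.normal(size=(30, 3)) * 5
        mobile = rng.normal(size=(20, 3)) * 5 + 30
        frames = np.stack([
            np.vstack([rigid, mobile + rng.normal(0, sigma, mobile.shape)])
            for _ in range(5000)])
        traj = Trajectory(frames)
        fit = AtomSelection(np.arange(30))
        measure = AtomSelection(np.arange(30, 50))
        ref = np.vstack([rigid, mobile])
        series = g.rmsd_series(traj, fit, measure, reference=ref)
        assert np.mean(series.values**2) == pytest.approx(3 * sigma**2, rel=0.05)


class TestPerResidueRmsd:
    def test_static_trajectory_all_zero(self, bundle):
        system, ref = bundle
        traj = Trajectory(np.stack([ref] * 3))
        fit = g.select(system, "protein and name CA")
        rmap = g.per_residue_rmsd(traj, system, ref, fit)
        assert np.nanmax(rmap.values) < 1e-10

    def test_planted_single_residue_shift(self, bundle):
        system, ref = bundle
        moved = ref.copy()
        idx = g.select(system, "PS1 and resid 200").indices
        moved[idx] += [3.0, 0.0, 0.0]
        traj = Trajectory(np.stack([moved] * 4))
        fit = g.select(system, "APH1 and name CA")      # fit far from the shift
        rmap = g.per_residue_rmsd(traj, system, ref, fit)
        row = rmap.residues.index("PS1:200")
        np.testing.assert_allclose(rmap.values[row], 3.0, atol=0.01)
        others = np.delete(rmap.values, row, axis=0)
        assert np.nanmax(others) < 0.01

    def test_consistency_with_bfactors(self, protein_run):
        """Against the trajectory-mean reference, the frame-mean squared
        per-residue RMSD equals (3/8pi^2) B of that residue's CA."""
        _, system, traj, _ = protein_run
        fit = g.select(system, "protein and name CA")
        ref = g.mean_structure(traj, fit)
        rmap = g.per_residue_rmsd(traj, system, ref, fit)
        prof = g.bfactors(traj, system, fit, fit, grouping="residue")
        b_by_key = prof.as_dict()
        msd_rows = np.nanmean(rmap.values**2, axis=1)
        expected = np.array([b_by_key[k] for k in rmap.residues]) / B_PREFACTOR
        np.testing.assert_allclose(msd_rows, expected, rtol=1e-6)

    def test_noise_subtract(self):
        a = g.ResidueRmsdMap(residues=["PS1:1", "PS1:2"], values=np.full((2, 5), 1.0))
        b = g.ResidueRmsdMap(residues=["PS1:1", "PS1:2"], values=np.full((2, 5), 1.4))
        out = g.rmsd_noise_subtract(a, b)
        np.testing.assert_allclose(out.values, 0.4)
        zero = g.rmsd_noise_subtract(a, a)
        np.testing.assert_allclose(zero.values, 0.0)
        with pytest.raises(ValueError):
            g.rmsd_noise_subtract(a, g.ResidueRmsdMap(residues=["PS1:1"],
                                                      values=np.ones((1, 5))))

    def test_cross_map_exposes_shifted_residue(self, bundle, rng):
        """Two fluctuation-matched trajectories, one residue shifted: only
        that row survives the noise subtraction."""
        system, ref = bundle
        fit = g.select(system, "APH1 and name CA")
        shifted_ref = ref.copy()
        idx = g.select(system, "PS1 and resid 150").indices
        shifted_ref[idx] += [2.0, 0, 0]
        frames_a = np.stack([ref + rng.normal(0, 0.2, ref.shape) for _ in range(40)])
        traj = Trajectory(frames_a)
        self_map = g.per_residue_rmsd(traj, system, ref, fit)
        cross_map = g.per_residue_rmsd(traj, system, shifted_ref, fit)
        out = g.rmsd_noise_subtract(self_map, cross_map)
        row = out.residues.index("PS1:150")
        assert np.nanmean(out.values[row]) > 1.0
        others = np.delete(out.values, row, axis=0)
        assert np.nanmean(others) < 0.3


class TestBfactors:
    def test_static_trajectory_zero(self, bundle):
        system, ref = bundle
        traj = Trajectory(np.stack([ref] * 4))
        sel = g.select(system, "protein and name CA")
        prof = g.bfactors(traj, system, sel, sel)
        assert np.max(prof.bfactor) < 1e-10

    def test_isotropic_jitter_closed_form(self, rng):
        """sigma = 0.5 Å per coordinate → B = 8 pi^2 * 0.25 ≈ 19.74 Å².

        The fit absorbs 6 rigid degrees of freedom, biasing B by a factor
        (1 - 6/3N); 200 atoms keep that within 1%."""
        base = rng.normal(size=(200, 3)) * 8
        frames = base[None] + rng.normal(0, 0.5, size=(10_000, 200, 3))
        traj = Trajectory(frames)
        system_stub = _stub_system(200)
        sel = AtomSelection(np.arange(200))
        prof = g.bfactors(traj, system_stub, sel, sel, grouping="atom")
        assert prof.bfactor.mean() == pytest.approx(8 * np.pi**2 * 0.25, rel=0.05)

    def test_trapped_below_diffusive(self, rng):
        """Planted tethered atoms have strictly lower B than random walkers."""
        n_frames = 400
        tethered = rng.normal(0, 0.5, size=(n_frames, 5, 3))
        steps = rng.normal(0, 1.0, size=(n_frames, 5, 3))
        walkers = np.cumsum(steps, axis=0)
        anchor = rng.normal(size=(4, 3)) * 20
        frames = np.concatenate(
            [np.broadcast_to(anchor, (n_frames, 4, 3)), tethered + 30, walkers - 30],
            axis=1)
        traj = Trajectory(frames.copy())
        system_stub = _stub_system(14)
        fit = AtomSelection(np.arange(4))
        prof = g.bfactors(traj, system_stub, fit, AtomSelection(np.arange(4, 14)),
                          grouping="atom", reference=0)
        b = prof.bfactor
        assert b[:5].max() < b[5:].min()


def _stub_system(n):
    return g.MolecularSystem(
        atom_ids=np.arange(n), atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object), masses=np.full(n, 12.0),
        residue_ids=np.arange(1, n + 1),
        residue_names=np.array(["ALA"] * n, dtype=object),
        subunit_of=np.array(["PS1"] * n, dtype=object))


class TestRadiusOfGyration:
    def test_two_points(self):
        traj = Trajectory(np.array([[[0, 0, 0], [2, 0, 0]]], dtype=float))
        rg = g.radius_of_gyration(traj, AtomSelection([0, 1]))
        assert rg.values[0] == pytest.approx(1.0)

    def test_unit_cube_vertices(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                           dtype=float)
        rg = g.radius_of_gyration(Trajectory(corners[None]), AtomSelection(range(8)))
        assert rg.values[0] == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_rigid_invariance_and_scaling(self, rng):
        pts = rng.normal(size=(15, 3))
        sel = AtomSelection(np.arange(15))
        base = g.radius_of_gyration(Trajectory(pts[None]), sel).values[0]
        R = Rotation.random(random_state=np.random.RandomState(9)).as_matrix()
        moved = g.radius_of_gyration(Trajectory((pts @ R.T + 7)[None]), sel).values[0]
        scaled = g.radius_of_gyration(Trajectory((2.5 * pts)[None]), sel).values[0]
        assert moved == pytest.approx(base, rel=1e-12)
        assert scaled == pytest.approx(2.5 * base, rel=1e-12)

    def test_planted_compaction_ratio(self, rng):
        pts = rng.normal(size=(30, 3)) * 6
        com = pts.mean(0)
        frames = np.concatenate([
            pts[None] + rng.normal(0, 0.05, (200, 30, 3)),
            (com + 0.98 * (pts - com))[None] + rng.normal(0, 0.05, (200, 30, 3)),
        ])
        rg = g.radius_of_gyration(Trajectory(frames), AtomSelection(np.arange(30)))
        ratio = rg.values[200:].mean() / rg.values[:200].mean()
        assert ratio == pytest.approx(0.98, abs=0.005)
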