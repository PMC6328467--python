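"""Tilt protocols, distances/angles, state segmentation, H-bond/bridge."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gsecdyn as g
from gsecdyn.core_io import AtomSelection, TimeSeries, Trajectory
from gsecdyn.geometry_states import angle_to_z, least_squares_changepoint
from gsecdyn.synthetic_data import SyntheticSpec, TiltWobbleSpec, generate


def ideal_helix(n=20, rise=1.5, twist=100.0, radius=2.3):
    t = np.arange(n)
    ang = np.radians(twist * t)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])


class TestHelixAxis:
    def test_helix_along_z(self):
        axis = g.helix_axis(ideal_helix())
        assert angle_to_z(axis) < 0.5

    def test_rotation_equivariance(self):
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        axis = g.helix_axis(ideal_helix() @ R.T)
        assert angle_to_z(axis) == pytest.approx(30.0, abs=0.5)

    def test_matches_line_fit_oracle_with_noise(self, rng):
        pts = ideal_helix(30) + rng.normal(0, 0.3, size=(30, 3))
        axis = g.helix_axis(pts)
        # independent oracle: least-squares 3D line fit via per-axis
        # regression on the arc-length parameter
        t = np.arange(30, dtype=float)
        t -= t.mean()
        centered = pts - pts.mean(0)
        slope = (t[:, None] * centered).sum(0) / (t**2).sum()
        oracle = slope / np.linalg.norm(slope)
        angle = np.degrees(np.arccos(np.clip(abs(axis @ oracle), -1, 1)))
        assert angle < 1.0

    def test_orientation_follows_chain_direction(self):
        pts = ideal_helix()
        up = g.helix_axis(pts)
        down = g.helix_axis(pts[::-1])
        assert up[2] > 0 > down[2]

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            g.helix_axis(np.zeros((5, 3)))


class TestDomainAxis:
    def test_vertical(self):
        axis = g.domain_axis_com(np.array([[0, 0, 10.0]]), np.array([[0, 0, 0.0]]))
        np.testing.assert_allclose(axis, [0, 0, 1])

    def test_tilted_bundle(self, rng):
        top = rng.normal(size=(8, 3)) + [0, 0, 15]
        bottom = rng.normal(size=(8, 3))
        R = Rotation.from_euler("y", 12, degrees=True).as_matrix()
        a0 = g.domain_axis_com(top, bottom)
        a1 = g.domain_axis_com(top @ R.T, bottom @ R.T)
        np.testing.assert_allclose(a1, R @ a0, atol=1e-12)   # axis co-rotates

    def test_matches_direct_summation(self, rng):
        top = rng.normal(size=(6, 3))
        bottom = rng.normal(size=(5, 3)) - 10
        v = top.mean(0) - bottom.mean(0)
        np.testing.assert_allclose(g.domain_axis_com(top, bottom),
                                   v / np.linalg.norm(v), atol=1e-12)


class TestTiltSeries:
    def test_identical_structures_zero_spread(self, bundle):
        system, ref = bundle
        stack = np.stack([ref] * 5)
        fit = g.select(system, "PS1 and name CA")
        helix = g.select(system, "PEN2-H3 and name CA")
        result = g.tilt_series(stack, fit, helix)
        assert result.spread < 1e-8

    def test_planted_wobble_recovery(self):
        spec = SyntheticSpec(n_frames=1000, transition=None,
                             tilt_wobble=TiltWobbleSpec("PEN2-H3", 20.0, 2.0),
                             solvent=None, lipids=None)
        system, traj, truth = generate(spec, seed=31)
        fit = g.select(system, "PS1 and name CA")
        helix = g.select(system, "PEN2-H3 and name CA")
        result = g.tilt_series(traj, fit, helix)
        assert np.nanmean(result.angles) == pytest.approx(20.0, abs=0.5)
        assert result.spread == pytest.approx(2.0, abs=0.2)

    def test_unresolved_member_flagged(self, bundle):
        system, ref = bundle
        broken = ref.copy()
        helix = g.select(system, "PEN2-H3 and name CA")
        broken[helix.indices] = np.nan
        stack = [ref, ref, broken]
        fit = g.select(system, "PS1 and name CA")
        # NaNs must not poison the fit selection
        assert not np.intersect1d(fit.indices, helix.indices).size
        result = g.tilt_series(np.stack(stack), fit, helix)
        assert np.isnan(result.angles[2]) and np.isfinite(result.angles[:2]).all()


class TestDistanceAngle:
    def test_hand_values(self):
        coords = np.array([[[0, 0, 0], [3, 4, 0], [0, 0, 0]]], dtype=float)
        traj = Trajectory(coords)
        d = g.distance_series(traj, AtomSelection([0]), AtomSelection([1]))
        assert d.values[0] == pytest.approx(5.0)
        d0 = g.distance_series(traj, AtomSelection([0]), AtomSelection([2]))
        assert d0.values[0] == pytest.approx(0.0)

    def test_minimum_image(self):
        coords = np.array([[[1, 0, 0], [19, 0, 0]]], dtype=float)
        traj = Trajectory(coords, box=np.array([[20.0, 20.0, 20.0]]))
        d = g.distance_series(traj, AtomSelection([0]), AtomSelection([1]))
        assert d.values[0] == pytest.approx(2.0)

    def test_angles_hand_and_oracle(self, rng):
        coords = np.array([[[1, 0, 0], [0, 0, 0], [-1, 0, 0]],
                           [[1, 0, 0], [0, 0, 0], [0, 1, 0]]], dtype=float)
        traj = Trajectory(coords)
        a = g.angle_series(traj, AtomSelection([0]), AtomSelection([1]), AtomSelection([2]))
        np.testing.assert_allclose(a.values, [180.0, 90.0], atol=1e-9)
        # random triples vs direct arccos
        pts = rng.normal(size=(30, 3, 3)) * 5
        traj = Trajectory(pts)
        series = g.angle_series(traj, AtomSelection([0]), AtomSelection([1]),
                                AtomSelection([2]))
        v1 = pts[:, 0] - pts[:, 1]
        v2 = pts[:, 2] - pts[:, 1]
        expected = np.degrees(np.arccos(np.clip(
            np.sum(v1 * v2, 1) / np.linalg.norm(v1, axis=1) / np.linalg.norm(v2, axis=1),
            -1, 1)))
        np.testing.assert_allclose(series.values, expected, atol=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(10, 4, 3)) * 8
        R = Rotation.random(random_state=np.random.RandomState(2)).as_matrix()
        moved = pts @ R.T + [3, -1, 2]
        for fn, sels in ((g.distance_series, (AtomSelection([0]), AtomSelection([1]))),
                         (g.angle_series, (AtomSelection([0]), AtomSelection([1]),
                                           AtomSelection([2])))):
            a = fn(Trajectory(pts), *sels).values
            b = fn(Trajectory(moved), *sels).values
            np.testing.assert_allclose(a, b, atol=1e-6)


class TestSegmentation:
    def test_flat_series_single_state(self):
        seg = g.segment_states(TimeSeries(np.full(300, 9.0), "Å"), buffer=10, window=20)
        assert seg.transition_frame is None
        assert set(seg.labels) == {"inactive"}

    def test_planted_step_recovery(self, rng):
        y = np.concatenate([rng.normal(8.0, 0.7, 1000), rng.normal(6.0, 1.0, 1000)])
        seg = g.segment_states(TimeSeries(y, "Å", "d"), buffer=50, window=100)
        assert abs(seg.transition_frame - 1000) <= 25
        stats = seg.per_state["d"]
        assert stats["inactive"]["mean"] == pytest.approx(8.0, abs=0.1)
        assert stats["active"]["mean"] == pytest.approx(6.0, abs=0.1)

    def test_changepoint_matches_exhaustive_oracle(self, rng):
        for trial in range(5):
            y = np.concatenate([rng.normal(5, 1, rng.integers(20, 200)),
                                rng.normal(rng.uniform(2, 8), 1, rng.integers(20, 200))])
            costs = [np.var(y[:k]) * k + np.var(y[k:]) * (len(y) - k)
                     for k in range(1, len(y))]
            assert least_squares_changepoint(y) == int(np.argmin(costs)) + 1

    def test_orientation_rule_higher_mean_inactive(self, rng):
        up = np.concatenate([rng.normal(6, 0.1, 200), rng.normal(9, 0.1, 200)])
        seg = g.segment_states(TimeSeries(up, "Å"), buffer=5, window=10)
        assert seg.labels[0] == "active" and seg.labels[-1] == "inactive"

    def test_partition_identity(self, rng):
        y = np.concatenate([rng.normal(9, 0.5, 300), rng.normal(8, 0.5, 300)])
        series = TimeSeries(y, "Å", "d")
        seg = g.segment_states(series, buffer=30, window=50)
        stats = seg.per_state["d"]
        keep = seg.labels != "buffer"
        weighted = sum(stats[s]["mean"] * stats[s]["n"] for s in ("inactive", "active"))
        total = sum(stats[s]["n"] for s in ("inactive", "active"))
        assert weighted / total == pytest.approx(y[keep].mean(), abs=1e-10)

    def test_buffer_surrounds_transition(self, rng):
        y = np.concatenate([rng.normal(9, 0.3, 200), rng.normal(7, 0.3, 200)])
        seg = g.segment_states(TimeSeries(y, "Å"), buffer=20, window=30)
        cp = seg.transition_frame
        assert set(seg.labels[cp - 20:cp + 20]) == {"buffer"}
        assert seg.labels[cp - 21] != "buffer" and seg.labels[cp + 20] != "buffer"


class TestHbondAndBridge:
    def _geometry(self, oo_dist):
        # two carboxyl oxygens facing each other plus one water position slot
        coords = np.array([[[0, 0, 0], [oo_dist, 0, 0], [oo_dist / 2, 0, 0]]])
        return Trajectory(coords.astype(float))

    def test_bonded_and_not_bonded(self):
        donor, acceptor = AtomSelection([0]), AtomSelection([1])
        assert g.hbond_fraction(self._geometry(2.8), donor, acceptor).fraction == 1.0
        assert g.hbond_fraction(self._geometry(4.5), donor, acceptor).fraction == 0.0

    def test_angle_criterion_with_hydrogen(self):
        # D-H···A nearly linear (bonded) vs H pointing away (not bonded)
        coords = np.array([
            [[0, 0, 0], [2.8, 0, 0], [1.0, 0, 0]],
            [[0, 0, 0], [2.8, 0, 0], [-1.0, 0, 0]],
        ], dtype=float)
        traj = Trajectory(coords)
        stats = g.hbond_fraction(traj, AtomSelection([0]), AtomSelection([1]),
                                 hydrogens=AtomSelection([2]))
        assert stats.fraction == 0.5

    def test_bridge_geometry(self):
        oa, ob, w = AtomSelection([0]), AtomSelection([1]), AtomSelection([2])
        bridged = g.water_bridge_stats(self._geometry(6.0), oa, ob, w)
        assert bridged.fraction == 1.0   # water midway, 3.0 Å from both
        apart = g.water_bridge_stats(self._geometry(7.4), oa, ob, w)
        assert apart.fraction == 0.0     # 3.7 Å from each side exceeds cutoff

    def test_planted_hbond_fraction_recovered(self, small_study):
        _, system, traj, truth = small_study
        a = g.residue_site(system, "PS1", 257, "CA")
        b = g.residue_site(system, "PS1", 385, "CA")
        d = g.distance_series(traj, a, b, label="dCA")
        seg = g.segment_states(d, buffer=20, window=50)
        oa = g.select(system, "PS1 and resid 257 and name OD1,OD2")
        ob = g.select(system, "PS1 and resid 385 and name OD1,OD2")
        active = seg.frames_of("active")
        stats = g.hbond_fraction(traj, oa, ob, frames=active, companion=d)
        planted = truth.planted["catalytic"]
        n = len(active)
        tol = 3 * np.sqrt(0.26 * 0.74 / n)
        assert stats.fraction == pytest.approx(planted["hbond_fraction_active"], abs=tol)
        assert stats.companion_mean == pytest.approx(planted["ca_hbond"][0], abs=0.15)

    def test_planted_bridge_conditional_distance(self, small_study):
        _, system, traj, truth = small_study
        a = g.residue_site(system, "PS1", 257, "CA")
        b = g.residue_site(system, "PS1", 385, "CA")
        d = g.distance_series(traj, a, b, label="dCA")
        seg = g.segment_states(d, buffer=20, window=50)
        waters = g.select(system, "WATER and name O")
        oa = g.select(system, "PS1 and resid 257 and name OD1,OD2")
        ob = g.select(system, "PS1 and resid 385 and name OD1,OD2")
        stats = g.water_bridge_stats(traj, oa, ob, waters,
                                     frames=seg.frames_of("active"), companion=d)
        planted = truth.planted["catalytic"]
        assert stats.companion_mean == pytest.approx(planted["ca_bridged"][0], abs=0.15)
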