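"""Superposition, rotation decomposition, domain geometry, and helix math."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from protofil.errors import GeometryError, InsufficientDataError, SelectionError
from protofil.geometry import (
    compose_euler,
    decompose_euler,
    decompose_interface_rotation,
    delta_rmsf,
    domain_rotation_angle,
    filament_frame,
    interdomain_distance,
    kabsch,
    rmsd_series,
    rmsf,
    superpose,
    twist_pitch,
)
from protofil.io import Structure, Trajectory, select
from protofil.synth import ClusterSpec, SubunitTemplate, TrajectorySpec, build_filament, generate_trajectory


def cloud(rng, n=12):
    return rng.normal(0, 5, (n, 3))


class TestKabsch:
    def test_identity(self, rng):
        x = cloud(rng)
        R, t, r = kabsch(x, x)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_recovers_known_rotation(self, rng):
        x = cloud(rng)
        R_true = Rotation.from_euler("xyz", [25, -10, 40], degrees=True).as_matrix()
        y = x @ R_true.T + np.array([1.0, -2.0, 3.0])
        R, t, r = kabsch(x, y)
        assert np.allclose(R, R_true, atol=1e-8)
        assert r == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_proper_rotation_on_near_reflection(self, rng):
        # mirrored cloud: best proper rotation must still have det +1
        x = cloud(rng)
        y = x * np.array([1, 1, -1])
        R, _, _ = kabsch(x, y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_errors(self, rng):
        x = cloud(rng)
        with pytest.raises(GeometryError):
            kabsch(x, x[:-1])
        with pytest.raises(InsufficientDataError):
            kabsch(x[:2], x[:2])
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(GeometryError):
            kabsch(line, line)

    def test_matches_brute_force_on_distorted_square(self):
        """Minimal RMSD must agree with direct minimisation over rotations."""
        ref = np.array([[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0.3]], float)
        mob = np.array([[1.1, 0.9, 0], [-1, 1.2, 0.1], [-0.9, -1, 0], [1, -1.1, 0.2]])

        def cost(v):
            R = Rotation.from_rotvec(v).as_matrix()
            m = mob - mob.mean(0)
            r = ref - ref.mean(0)
            return np.sqrt(((m @ R.T - r) ** 2).sum() / len(ref))

        best = np.inf
        for x0 in ([0, 0, 0], [1, 0, 0], [0, 2, 0], [1, 1, 1], [-1, 2, 0.5]):
            res = minimize(cost, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = min(best, res.fun)
        _, _, rmsd = kabsch(mob, ref)
        assert rmsd == pytest.approx(best, abs=1e-6)


class TestRmsdRmsf:
    def make_traj(self, frames, names=None):
        n = frames.shape[1]
        ref = Structure(
            coords=frames[0],
            atom_name=np.array(["CA"] * n),
            res_name=np.array(["GLY"] * n),
            res_id=np.arange(1, n + 1),
            chain_id=np.array(["A"] * n),
        )
        return Trajectory(reference=ref, frames=frames, frame_dt=0.1)

    def test_static_and_translated_frames_are_zero(self, rng):
        x = cloud(rng, 8)
        frames = np.stack([x, x + np.array([5.0, 0, 0]), x])
        traj = self.make_traj(frames)
        sel = np.arange(8)
        assert np.allclose(rmsd_series(traj, traj.reference, sel), 0, atol=1e-10)
        assert np.allclose(rmsf(traj, sel), 0, atol=1e-8)

    def test_rmsd_matches_direct_recomputation(self, rng):
        x = cloud(rng, 10)
        frames = x[None] + rng.normal(0, 0.5, (6, 10, 3))
        traj = self.make_traj(frames)
        sel = np.arange(10)
        got = rmsd_series(traj, traj.reference, sel)
        # independent oracle: scipy align_vectors RSSD per frame
        for f in range(6):
            a = frames[f] - frames[f].mean(0)
            b = frames[0] - frames[0].mean(0)
            _, rssd = Rotation.align_vectors(b, a)
            assert got[f] == pytest.approx(rssd / np.sqrt(10), abs=1e-10)

    def test_rmsf_breathing_mode_hand_computed(self):
        # radial breathing is orthogonal to rigid-body modes: superposition
        # stays the identity and the RMSF is sqrt(mean squared deviation)
        base = np.array([[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]], float)
        d = 0.3
        frames = np.stack([base, base * (1 + d), base * (1 - d)])
        traj = self.make_traj(frames)
        got = rmsf(traj, np.arange(4))
        expect = np.sqrt((0 + (d * np.sqrt(2)) ** 2 * 2) / 3)
        assert np.allclose(got, expect, atol=1e-8)

    def test_rmsf_flags_jittered_residue(self, rng):
        x = cloud(rng, 10)
        frames = x[None] + rng.normal(0, 0.1, (20, 10, 3))
        frames[:, 4, :] += rng.normal(0, 2.0, (20, 3))
        traj = self.make_traj(frames)
        assert np.argmax(rmsf(traj, np.arange(10))) == 4

    def test_rigid_motion_invariance(self, rng):
        x = cloud(rng, 9)
        frames = x[None] + rng.normal(0, 0.4, (5, 9, 3))
        traj = self.make_traj(frames)
        sel = np.arange(9)
        R = Rotation.from_euler("zyx", [30, 50, -20], degrees=True).as_matrix()
        moved = self.make_traj(frames @ R.T + np.array([10.0, -3.0, 7.0]))
        assert np.allclose(rmsd_series(traj, traj.reference, sel),
                           rmsd_series(moved, moved.reference, sel), atol=1e-8)
        assert np.allclose(rmsf(traj, sel), rmsf(moved, sel), atol=1e-6)

    def test_single_frame_rmsf_raises(self, rng):
        traj = self.make_traj(cloud(rng, 5)[None])
        with pytest.raises(InsufficientDataError):
            rmsf(traj, np.arange(5))


class TestDeltaRmsf:
    def test_zero_and_boundary(self):
        a = np.array([0.5, 1.0, 2.0])
        d, flags = delta_rmsf(a, a)
        assert np.allclose(d, 0) and not flags.any()
        b = np.array([0.5, 1.0, 0.8])
        d, flags = delta_rmsf(a, b)
        assert list(flags) == [False, False, True]          # Δ=1.2 flagged
        d, flags = delta_rmsf(np.array([2.0]), np.array([1.0]))
        assert not flags.any()                              # Δ=1.0 exactly: strict
        with pytest.raises(GeometryError):
            delta_rmsf(a, a[:-1])


class TestFilamentFrame:
    def test_straight_trimer_axes(self, trimer):
        s, m = trimer
        fr = filament_frame(s, m)
        assert np.allclose(fr.z, [0, 0, 1], atol=1e-10)
        # C-domain offset is along +x by construction
        assert np.allclose(fr.x, [1, 0, 0], atol=1e-10)
        B = fr.basis
        assert np.abs(B.T @ B - np.eye(3)).max() < 1e-10
        assert np.linalg.det(B) == pytest.approx(1.0, abs=1e-10)


class TestEulerDecomposition:
    def test_identity_and_pure_twist(self):
        theta, gimbal = decompose_euler(np.eye(3))
        assert np.allclose(theta, 0, atol=1e-12) and not gimbal
        theta, _ = decompose_euler(compose_euler([10.0, 0, 0]))
        assert np.allclose(theta, [10, 0, 0], atol=1e-8)

    def test_round_trip_many_random_triples(self, rng):
        """compose∘decompose = identity over 10⁴ triples away from gimbal."""
        t1 = rng.uniform(-179, 179, 10_000)
        t2 = rng.uniform(-85, 85, 10_000)
        t3 = rng.uniform(-179, 179, 10_000)
        triples = np.column_stack([t1, t2, t3])
        R = Rotation.from_euler("ZXY", triples, degrees=True)
        back = R.as_euler("ZXY", degrees=True)
        assert np.abs(back - triples).max() < 1e-8
        # and the matrices themselves round trip through our wrappers
        for th in triples[:50]:
            rec, _ = decompose_euler(compose_euler(th))
            assert np.abs(compose_euler(rec) - compose_euler(th)).max() < 1e-8

    def test_gimbal_flag(self):
        _, gimbal = decompose_euler(compose_euler([10.0, 89.95, 5.0]))
        assert gimbal


class TestInterfaceRotation:
    def test_reported_mean_triples_round_trip_noiselessly(self, trimer):
        """Imposed GDP and GTP ensemble-mean angle triples are recovered
        exactly by the decomposition."""
        s, m = trimer
        for triple in [(-24.7, 13.7, 3.8), (-21.2, 2.8, 0.6)]:
            spec = TrajectorySpec(
                mode="custom", n_frames=2, noise_sd=0.0, angle_noise_sd=0.0,
                clusters=(ClusterSpec(label="x", theta=triple),), seed=3)
            traj, _ = generate_trajectory(spec)
            for which in ("top", "bottom"):
                got = decompose_interface_rotation(traj, m, which, reference=s)
                assert np.allclose(got.theta[0], triple, atol=1e-6)

    def test_noisy_recovery_within_one_degree(self, trimer):
        s, m = trimer
        spec = TrajectorySpec(
            mode="custom", n_frames=30, noise_sd=0.3, angle_noise_sd=0.0,
            clusters=(ClusterSpec(label="x", theta=(-20.0, 10.0, 2.0)),), seed=9)
        traj, log = generate_trajectory(spec)
        got = decompose_interface_rotation(traj, m, "top", reference=s)
        err = np.abs(got.theta - log.theta_top)
        assert err.mean() < 1.0

    def test_unknown_subunit_raises(self, trimer):
        s, m = trimer
        spec = TrajectorySpec(mode="GTP", n_frames=2, seed=1)
        traj, _ = generate_trajectory(spec)
        with pytest.raises(SelectionError):
            decompose_interface_rotation(traj, m, "apex", reference=s)


class TestInterdomainDistance:
    def test_reference_equals_template_separation(self, trimer):
        s, m = trimer
        traj = Trajectory(reference=s, frames=s.coords[None], frame_dt=0.1)
        for lab in m.labels:
            d = interdomain_distance(traj, m, lab).distances
            assert d[0] == pytest.approx(30.0, abs=1e-9)

    def test_closure_reduces_distance_exactly(self, trimer):
        s, m = trimer
        spec = TrajectorySpec(
            mode="custom", n_frames=2, noise_sd=0.0, angle_noise_sd=0.0,
            clusters=(ClusterSpec(label="c", theta=(0, 0, 0), closure_delta=3.0,
                                  closure_subunits=("middle",)),), seed=1)
        traj, _ = generate_trajectory(spec)
        assert interdomain_distance(traj, m, "middle").distances[0] == pytest.approx(27.0, abs=1e-9)

    def test_matches_direct_centroid_arithmetic(self, trimer, rng):
        s, m = trimer
        frames = s.coords[None] + rng.normal(0, 0.4, (4,) + s.coords.shape)
        traj = Trajectory(reference=s, frames=frames, frame_dt=0.1)
        got = interdomain_distance(traj, m, "top").distances
        n_idx = select(s, m, subunit="top", domain="N")
        c_idx = select(s, m, subunit="top", domain="C")
        for f in range(4):
            expect = np.linalg.norm(frames[f][n_idx].mean(0) - frames[f][c_idx].mean(0))
            assert got[f] == pytest.approx(expect, abs=1e-12)

    def test_invariant_under_rigid_motion_of_subunit(self, trimer, rng):
        s, m = trimer
        idx = select(s, m, subunit="top")
        moved = s.coords.copy()
        R = Rotation.from_euler("xyz", [17, -33, 5], degrees=True).as_matrix()
        cent = moved[idx].mean(0)
        moved[idx] = (moved[idx] - cent) @ R.T + cent + np.array([3.0, 1.0, -2.0])
        traj = Trajectory(reference=s, frames=moved[None], frame_dt=0.1)
        assert interdomain_distance(traj, m, "top").distances[0] == pytest.approx(30.0, abs=1e-9)


class TestDomainRotation:
    def test_zero_and_imposed_angles(self, trimer):
        s, m = trimer
        sub = s
        assert domain_rotation_angle(sub, sub, m, "bottom") == pytest.approx(0.0, abs=1e-9)
        for angle in (19.0, 90.0):
            c_idx = select(s, m, subunit="bottom", domain="C")
            axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
            R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
            coords = s.coords.copy()
            cent = coords[c_idx].mean(0)
            coords[c_idx] = (coords[c_idx] - cent) @ R.T + cent
            got = domain_rotation_angle(s, s.with_coords(coords), m, "bottom")
            assert got == pytest.approx(angle, abs=1e-6)


class TestTwistPitch:
    def test_full_convention(self):
        # 6 subunits per turn at 4 nm rise: pitch 24 nm, twist 60° (full)
        assert twist_pitch(4.0, 24.0, "pitch_to_twist", "full") == pytest.approx(60.0)

    def test_half_convention_crystal_helix(self):
        assert twist_pitch(4.0, 24.0, "pitch_to_twist", "half") == pytest.approx(30.0)

    def test_round_trip(self):
        tw = twist_pitch(4.0, 150.0, "pitch_to_twist", "half")
        assert twist_pitch(4.0, tw, "twist_to_pitch", "half") == pytest.approx(150.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(GeometryError):
            twist_pitch(-1.0, 24.0, "pitch_to_twist")
        with pytest.raises(GeometryError):
            twist_pitch(4.0, 24.0, "sideways")
        with pytest.raises(GeometryError):
            twist_pitch(4.0, 24.0, "pitch_to_twist", "thirds")
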