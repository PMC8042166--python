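"""Distance-feature SVD, free-energy landscapes, adjusted regression,
and contact bookkeeping."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from protofil.ensemble import (
    PCProjection,
    adjusted_regression,
    contact_diff,
    contact_map,
    distance_features,
    fel,
    svd_project,
)
from protofil.errors import (
    DegeneratePredictorError,
    InvalidSpecificationError,
    SelectionError,
)
from protofil.io import Structure, Trajectory


def make_traj(frames):
    n = frames.shape[1]
    ref = Structure(coords=frames[0], atom_name=np.array(["CA"] * n),
                    res_name=np.array(["GLY"] * n), res_id=np.arange(1, n + 1),
                    chain_id=np.array(["A"] * n))
    return Trajectory(reference=ref, frames=frames, frame_dt=0.1)


def projection_from(points):
    points = np.asarray(points, float)
    return PCProjection(projections=points, components=np.zeros((2, 2)),
                        singular_values=np.zeros(2),
                        explained_variance=np.zeros(2), column_means=np.zeros(2))


def feature_matrix(mat):
    """FeatureMatrix over an arbitrary synthetic matrix (no atom-count tie)."""
    from protofil.ensemble import FeatureMatrix
    fm = FeatureMatrix.__new__(FeatureMatrix)
    fm.matrix = np.asarray(mat, float)
    fm.n_atoms = 0
    return fm


class TestDistanceFeatures:
    def test_column_count_and_hand_check(self):
        frames = np.array([
            [[0, 0, 0], [3, 0, 0], [0, 4, 0.0]],
            [[0, 0, 0], [1, 0, 0], [0, 0, 2.0]],
        ])
        fm = distance_features(make_traj(frames), np.arange(3))
        assert fm.matrix.shape == (2, 3)
        assert np.allclose(fm.matrix[0], [3.0, 4.0, 5.0])
        assert np.allclose(fm.matrix[1], [1.0, 2.0, np.sqrt(5)])

    def test_rigid_motion_invariance(self, rng):
        frames = rng.normal(0, 3, (4, 6, 3))
        R = Rotation.from_euler("zxz", [11, 62, -40], degrees=True).as_matrix()
        moved = frames @ R.T + np.array([4.0, 5.0, -6.0])
        a = distance_features(make_traj(frames), np.arange(6)).matrix
        b = distance_features(make_traj(moved), np.arange(6)).matrix
        assert np.abs(a - b).max() < 1e-9

    def test_too_few_atoms(self, rng):
        traj = make_traj(rng.normal(0, 1, (2, 4, 3)))
        with pytest.raises(SelectionError):
            distance_features(traj, np.array([0]))


class TestSvdProject:
    def test_rank_one_and_centering(self, rng):
        t = np.linspace(0, 1, 8)
        base = rng.normal(0, 1, 12)
        direction = rng.normal(0, 1, 12)
        fm = feature_matrix(base[None] + t[:, None] * direction[None])
        proj = svd_project(fm, k=2)
        assert proj.explained_variance[0] == pytest.approx(1.0, abs=1e-10)
        assert proj.explained_variance[1] == pytest.approx(0.0, abs=1e-10)
        centered = fm.matrix - proj.column_means
        assert np.abs(centered.mean(axis=0)).max() < 1e-10

    def test_full_reconstruction(self, rng):
        fm = feature_matrix(rng.normal(0, 2, (6, 10)))
        proj = svd_project(fm, k=6)
        recon = proj.projections @ proj.components + proj.column_means
        rel = np.abs(recon - fm.matrix).max() / np.abs(fm.matrix).max()
        assert rel < 1e-8

    def test_two_clusters_split_on_pc1(self, rng):
        labels = np.array([0] * 10 + [1] * 10)
        centers = np.array([np.zeros(8), np.full(8, 6.0)])
        fm = feature_matrix(centers[labels] + rng.normal(0, 0.3, (20, 8)))
        proj = svd_project(fm, k=2)
        pc1 = proj.projections[:, 0]
        assert len(set(np.sign(pc1[labels == 0]))) == 1
        assert set(np.sign(pc1[labels == 0])) != set(np.sign(pc1[labels == 1]))

    def test_k_beyond_rank_pads_with_warning(self, rng):
        fm = feature_matrix(np.tile(rng.normal(0, 1, 5), (3, 1)))  # identical frames
        with pytest.warns(UserWarning, match="rank"):
            proj = svd_project(fm, k=2)
        assert np.allclose(proj.projections, 0.0)


class TestFel:
    def test_identical_frames_single_minimum_at_zero(self):
        grid = fel(projection_from(np.zeros((50, 2))), smooth_sd=0)
        occ = np.isfinite(grid.free_energy)
        assert grid.free_energy[occ].min() == 0.0
        assert grid.n_minima == 1

    def test_flat_landscape_merges_to_one(self, rng):
        pts = rng.uniform(0, 1, (4000, 2))
        grid = fel(projection_from(pts))
        assert grid.n_minima == 1

    def test_three_gaussians_three_funnels(self, rng):
        centers = np.array([[0, 0], [6, 0], [0, 6.0]])   # ≥ 6 sd separation
        lab = rng.integers(0, 3, 1200)
        pts = centers[lab] + rng.normal(0, 1.0, (1200, 2))
        grid = fel(projection_from(pts))
        assert grid.n_minima == 3

    def test_min_over_occupied_is_zero_and_shift_invariant(self, rng):
        pts = rng.normal(0, 1, (500, 2))
        g1 = fel(projection_from(pts))
        g2 = fel(projection_from(pts + 17.0))
        occ = np.isfinite(g1.free_energy)
        assert g1.free_energy[occ].min() == 0.0
        assert np.allclose(g1.free_energy[occ], g2.free_energy[np.isfinite(g2.free_energy)])

    def test_invalid_bins(self):
        with pytest.raises(InvalidSpecificationError):
            fel(projection_from(np.zeros((5, 2))), n_bins=1)


class TestAdjustedRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        r = adjusted_regression(x, 2 * x, frame_dt=1.0)
        assert r.slope == pytest.approx(2.0)
        assert r.r == pytest.approx(1.0)
        assert r.p_adjusted == 0.0

    def test_effective_sample_size_rule(self, rng):
        x = rng.normal(0, 1, 4500)
        y = rng.normal(0, 1, 4500)
        r = adjusted_regression(x, y, frame_dt=0.1, decorrelation=1.0)
        assert r.n_eff == 450

    def test_reduces_to_classical_f_test(self, rng):
        x = rng.normal(0, 1, 40)
        y = 0.4 * x + rng.normal(0, 1, 40)
        ours = adjusted_regression(x, y, frame_dt=1.0, decorrelation=1.0)
        classical = stats.linregress(x, y)
        assert ours.p_adjusted == pytest.approx(classical.pvalue, rel=1e-9)

    def test_undersampled_flag(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        r = adjusted_regression(x, y, frame_dt=0.1, decorrelation=1.0)  # n_eff = 3
        assert r.undersampled and np.isnan(r.p_adjusted)

    def test_constant_predictor(self):
        with pytest.raises(DegeneratePredictorError):
            adjusted_regression(np.ones(10), np.arange(10.0), frame_dt=1.0)


def toy_peptide(positions):
    n = len(positions)
    return Structure(coords=np.asarray(positions, float),
                     atom_name=np.array(["CA"] * n),
                     res_name=np.array(["GLY"] * n),
                     res_id=np.arange(1, n + 1),
                     chain_id=np.array(["A"] * n))


class TestContacts:
    def test_cutoff_inclusion_and_sequence_separation(self):
        # residues 1 and 5 are 3 Å apart; 1 and 3 are closer but |i−j| < 3
        s = toy_peptide([[0, 0, 0], [10, 0, 0], [1.0, 0, 0], [30, 0, 0], [3.0, 0, 0]])
        sel = np.arange(5)
        assert (0, 4) in contact_map(s, sel, cutoff=4.5)
        assert (0, 4) not in contact_map(s, sel, cutoff=2.0)
        assert (0, 2) not in contact_map(s, sel, cutoff=4.5)

    def test_matches_exhaustive_oracle(self, rng):
        coords = rng.normal(0, 4, (12, 3))
        s = toy_peptide(coords)
        sel = np.arange(12)
        got = contact_map(s, sel, cutoff=5.0)
        expect = {(i, j) for i in range(12) for j in range(i + 3, 12)
                  if np.linalg.norm(coords[i] - coords[j]) <= 5.0}
        assert got == expect

    def test_contact_diff_gained_lost_and_persistence(self, rng):
        base = rng.normal(0, 6, (10, 3))
        base[7] = base[2] + np.array([2.0, 0, 0])      # persistent contact 2–7
        frames_a = np.repeat(base[None], 10, axis=0)
        # ensemble B: contact 2–7 broken in every frame
        broken = base.copy()
        broken[7] += np.array([50.0, 0, 0])
        frames_b = np.repeat(broken[None], 10, axis=0)
        ta, tb = make_traj(frames_a), make_traj(frames_b)
        diff = contact_diff(ta, tb, np.arange(10), cutoff=4.5)
        assert (2, 7) in diff.lost and (2, 7) not in diff.gained
        same = contact_diff(ta, ta, np.arange(10), cutoff=4.5)
        assert not same.gained and not same.lost

    def test_persistence_threshold_straddled(self, rng):
        base = rng.normal(0, 8, (8, 3))
        near = base.copy()
        near[6] = base[1] + np.array([2.0, 0, 0])
        far = base.copy()
        far[6] = base[1] + np.array([40.0, 0, 0])
        # 60% present < 0.7 threshold; 80% present ≥ threshold
        frames_60 = np.stack([near] * 6 + [far] * 4)
        frames_80 = np.stack([near] * 8 + [far] * 2)
        sel = np.arange(8)
        d60 = contact_diff(make_traj(frames_60), make_traj(frames_60), sel)
        d80 = contact_diff(make_traj(frames_80), make_traj(frames_80), sel)
        assert (1, 6) not in d60.present_a
        assert (1, 6) in d80.present_a
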