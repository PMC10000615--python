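import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdshift.errors import GeometryError
from mdshift.model import CA_SELECTION, Structure, Trajectory
from mdshift.superpose import kabsch, rmsd, rmsd_series

from .conftest import make_ca_chain
from .oracles import grid_min_rmsd


def random_rotation(rng) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        pts = rng.normal(0, 3, (8, 3))
        res = kabsch(pts, pts)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.translation, 0, atol=1e-10)
        assert res.rmsd == pytest.approx(0, abs=1e-12)

    def test_pure_translation_recovered(self, rng):
        pts = rng.normal(0, 3, (8, 3))
        shifted = pts + np.array([1.0, 2.0, 3.0])
        res = kabsch(shifted, pts)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.apply(shifted), pts, atol=1e-10)
        assert res.rmsd == pytest.approx(0, abs=1e-10)

    def test_known_rotation_recovered(self, rng):
        pts = rng.normal(0, 3, (10, 3))
        rot = random_rotation(rng)
        moved = pts @ rot.T + [4.0, -1.0, 2.0]
        res = kabsch(moved, pts)
        assert res.rmsd == pytest.approx(0, abs=1e-9)
        np.testing.assert_allclose(res.apply(moved), pts, atol=1e-8)

    def test_rotation_is_proper(self, rng):
        # a near-reflective correspondence must still yield det +1
        pts = rng.normal(0, 2, (6, 3))
        mirrored = pts * np.array([1, 1, -1])
        res = kabsch(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        rt = res.rotation @ res.rotation.T
        np.testing.assert_allclose(rt, np.eye(3), atol=1e-8)

    def test_matches_exhaustive_rotation_grid(self, rng):
        for _ in range(5):
            pts = rng.normal(0, 3, (6, 3))
            moved = pts @ random_rotation(rng).T + rng.normal(0, 0.1, (6, 3))
            ours = kabsch(moved, pts).rmsd
            brute = grid_min_rmsd(moved, pts)
            assert ours <= brute + 1e-12
            assert abs(ours - brute) < 1e-3

    def test_no_random_rotation_beats_kabsch(self, rng):
        pts = rng.normal(0, 3, (12, 3))
        moved = pts @ random_rotation(rng).T + rng.normal(0, 0.5, (12, 3))
        best = kabsch(moved, pts).rmsd
        m_c = moved - moved.mean(axis=0)
        t_c = pts - pts.mean(axis=0)
        rots = Rotation.random(1000, rng=rng).as_matrix()
        fitted = np.einsum("kij,nj->kni", rots, m_c)
        vals = np.sqrt(((fitted - t_c[None]) ** 2).sum(axis=2).mean(axis=1))
        assert best <= vals.min() + 1e-12

    def test_invariant_to_pre_rigid_motion_of_mobile(self, rng):
        pts = rng.normal(0, 3, (9, 3))
        moved = pts + rng.normal(0, 0.4, (9, 3))
        base_rmsd = kabsch(moved, pts).rmsd
        pre = moved @ random_rotation(rng).T + [10.0, -5.0, 3.0]
        assert kabsch(pre, pts).rmsd == pytest.approx(base_rmsd, abs=1e-8)

    def test_weights_bias_the_fit(self, rng):
        pts = rng.normal(0, 3, (6, 3))
        moved = pts.copy()
        moved[0] += [2.0, 0, 0]
        w = np.ones(6)
        w[0] = 1e-6  # nearly ignore the displaced point
        res = kabsch(moved, pts, weights=w)
        np.testing.assert_allclose(res.apply(moved)[1:], pts[1:], atol=1e-4)

    def test_too_few_points_raise(self):
        with pytest.raises(GeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_sets_warn_but_return_optimal_rmsd(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.warns(UserWarning, match="degenerate"):
            res = kabsch(line, line + [1.0, 0, 0])
        assert res.rmsd == pytest.approx(0, abs=1e-10)

    def test_cross_check_against_mdanalysis(self, rng):
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        pts = rng.normal(0, 3, (15, 3))
        moved = pts @ random_rotation(rng).T + rng.normal(0, 0.3, (15, 3))
        ours = kabsch(moved, pts).rmsd
        theirs = mda_rms.rmsd(moved, pts, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestPlainRmsd:
    def test_identical_sets_zero(self, rng):
        pts = rng.normal(size=(5, 3))
        assert rmsd(pts, pts) == 0

    def test_single_displaced_point_hand_value(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        b = a.copy()
        b[0, 0] += 2.0  # one of three points moved 2 A
        assert rmsd(a, b) == pytest.approx(np.sqrt(4 / 3), abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 7, 3))
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-14)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(GeometryError):
            rmsd(rng.normal(size=(5, 3)), rng.normal(size=(4, 3)))


class TestRmsdSeries:
    def test_copies_of_reference_give_zero(self, helix20):
        traj = Trajectory(helix20, np.stack([helix20.coords] * 5))
        series = rmsd_series(traj, helix20, CA_SELECTION)
        np.testing.assert_allclose(series, 0, atol=1e-10)

    def test_global_rotations_only_give_zero(self, helix20, rng):
        frames = np.stack(
            [
                helix20.coords @ random_rotation(rng).T + rng.normal(0, 5, 3)
                for _ in range(8)
            ]
        )
        series = rmsd_series(Trajectory(helix20, frames), helix20)
        np.testing.assert_allclose(series, 0, atol=1e-6)

    def test_growing_noise_gives_growing_series(self, helix20, rng):
        sigmas = np.linspace(0.05, 1.5, 40)
        frames = helix20.coords[None] + rng.normal(
            0, 1, (40, 20, 3)
        ) * sigmas[:, None, None]
        series = rmsd_series(Trajectory(helix20, frames), helix20)
        third = len(series) // 3
        assert series[:third].mean() < series[-third:].mean()
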