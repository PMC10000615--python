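import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdshift.ensemble import average_rmsf, average_structure, rmsf_profile
from mdshift.errors import AlignmentError, MDShiftError, WindowError
from mdshift.model import Trajectory
from mdshift.synthetic import SyntheticSpec, generate_condition

from .conftest import make_ca_chain


def gaussian_ensemble(n_res, n_frames, sigma, seed=11, global_motion=False):
    spec = SyntheticSpec(
        n_residues=n_res,
        n_frames=n_frames,
        seed=seed,
        sigma=sigma,
        global_motion=global_motion,
        replicates=1,
    )
    cond = generate_condition(spec)
    return cond.replicates[0], cond.base


class TestRmsfProfile:
    def test_static_trajectory_is_zero(self, helix20):
        traj = Trajectory(helix20, np.stack([helix20.coords] * 4))
        prof = rmsf_profile(traj, helix20)
        np.testing.assert_allclose(prof.values, 0, atol=1e-12)

    def test_single_frame_raises(self, helix20):
        traj = Trajectory(helix20, helix20.coords[None])
        with pytest.raises(MDShiftError):
            rmsf_profile(traj, helix20)

    def test_isotropic_gaussian_matches_closed_form(self):
        # sigma per axis 0.5 A -> RMSF = sigma * sqrt(3) = 0.8660 A.
        # A long chain keeps the rigid-body fit from absorbing noticeable
        # noise (the fit removes 6 of 3N degrees of freedom per frame).
        traj, base = gaussian_ensemble(310, 10_000, 0.5)
        prof = rmsf_profile(traj, base)
        np.testing.assert_allclose(
            prof.values, 0.5 * np.sqrt(3), rtol=0.02
        )

    def test_elevated_window_hosts_the_maximum(self):
        spec = SyntheticSpec(
            n_residues=220,
            n_frames=400,
            seed=5,
            sigma=0.3,
            flexible_windows=(((203, 211), 4.0),),
            global_motion=True,
            replicates=1,
        )
        cond = generate_condition(spec)
        prof = rmsf_profile(cond.replicates[0], cond.base)
        peak_residue = prof.residue_numbers[int(np.argmax(prof.values))]
        assert 203 <= peak_residue <= 211

    def test_invariant_to_one_global_rigid_motion(self, rng):
        traj, base = gaussian_ensemble(15, 200, 0.4)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = Trajectory(
            traj.topology, traj.frames @ rot.T + np.array([3.0, -2.0, 7.0])
        )
        a = rmsf_profile(traj, base).values
        b = rmsf_profile(moved, base).values
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestAverageRmsf:
    def test_identity_and_arithmetic_mean(self, helix20):
        traj = Trajectory(
            helix20, np.stack([helix20.coords] * 3)
        )
        prof = rmsf_profile(traj, helix20)
        same = average_rmsf([prof, prof])
        np.testing.assert_allclose(same.values, prof.values)
        assert same.replicate_count == 2

        a = prof
        b_vals = prof.values + 2.0
        from mdshift.ensemble import RMSFProfile

        b = RMSFProfile(prof.residue_numbers, b_vals, n_frames=3)
        mean = average_rmsf([a, b])
        np.testing.assert_allclose(mean.values, prof.values + 1.0)

    def test_permuted_residue_order_is_aligned(self, rng):
        from mdshift.ensemble import RMSFProfile

        resnums = np.arange(1, 21)
        vals = rng.uniform(0.1, 2.0, 20)
        perm = rng.permutation(20)
        a = RMSFProfile(resnums, vals, n_frames=10)
        b = RMSFProfile(resnums[perm], vals[perm], n_frames=10)
        mean = average_rmsf([a, b])
        np.testing.assert_allclose(mean.values, vals)

    def test_argument_permutation_invariance(self, rng):
        from mdshift.ensemble import RMSFProfile

        resnums = np.arange(1, 11)
        profs = [
            RMSFProfile(resnums, rng.uniform(0, 1, 10), n_frames=5)
            for _ in range(3)
        ]
        m1 = average_rmsf(profs)
        m2 = average_rmsf(profs[::-1])
        np.testing.assert_allclose(m1.values, m2.values)

    def test_mismatched_residues_raise(self):
        from mdshift.ensemble import RMSFProfile

        a = RMSFProfile(np.arange(1, 11), np.ones(10), n_frames=5)
        b = RMSFProfile(np.arange(2, 12), np.ones(10), n_frames=5)
        with pytest.raises(AlignmentError):
            average_rmsf([a, b])


class TestAverageStructure:
    def test_identical_frames_average_to_the_frame(self, helix20):
        traj = Trajectory(helix20, np.stack([helix20.coords] * 6))
        avg = average_structure(traj, (0, 5), helix20)
        np.testing.assert_allclose(avg.coords, helix20.coords, atol=1e-12)

    def test_alternating_rigid_offsets_cancel(self, helix20):
        d = np.array([0.7, -0.3, 1.1])  # rigid offset: overlay removes it
        frames = np.stack(
            [helix20.coords + (d if i % 2 == 0 else -d) for i in range(6)]
        )
        avg = average_structure(Trajectory(helix20, frames), (0, 5), helix20)
        np.testing.assert_allclose(avg.coords, helix20.coords, atol=1e-9)

    def test_full_window_of_motion_free_trajectory_is_frame_mean(self, helix20):
        # all frames identical -> fit is the identity (to rounding) and the
        # average equals the arithmetic frame mean
        frames = np.stack([helix20.coords] * 4)
        avg = average_structure(Trajectory(helix20, frames), (0, 3), helix20)
        np.testing.assert_allclose(avg.coords, frames.mean(axis=0), atol=1e-12)

    def test_overlay_recovers_base_under_global_motion(self):
        spec = SyntheticSpec(
            n_residues=40,
            n_frames=300,
            seed=9,
            sigma=0.3,
            global_motion=True,
            replicates=1,
        )
        cond = generate_condition(spec)
        traj = cond.replicates[0]
        avg = average_structure(traj, (0, 299), cond.base)
        err = np.linalg.norm(avg.coords - cond.base.coords, axis=1)
        assert err.max() < 0.15  # ~ sigma*sqrt(3)/sqrt(F) with headroom

        naive = traj.frames.mean(axis=0)
        naive_err = np.linalg.norm(naive - cond.base.coords, axis=1)
        assert naive_err.max() > 10 * err.max()

    def test_empty_or_invalid_window_raises(self, helix20):
        traj = Trajectory(helix20, np.stack([helix20.coords] * 3))
        with pytest.raises(WindowError):
            average_structure(traj, (2, 1), helix20)
        with pytest.raises(WindowError):
            average_structure(traj, (0, 5), helix20)
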