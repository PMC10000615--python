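import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdshift.errors import SelectionError, SpecValidationError, WindowError
from mdshift.model import Atom, Selection, Structure, Trajectory
from mdshift.probes import (
    PocketSpec,
    cavity_volume,
    compare_window_means,
    pair_distance_track,
)
from mdshift.synthetic import DisplacementEvent, SyntheticSpec, generate_condition

from .conftest import make_ca_chain, make_cage_structure
from .oracles import mc_cavity_volume


class TestDistanceTrack:
    def test_static_pair_constant(self, helix20):
        traj = Trajectory(helix20, np.stack([helix20.coords] * 5))
        track = pair_distance_track(traj, ((1, "CA"), (2, "CA")))
        d0 = np.linalg.norm(helix20.coords[0] - helix20.coords[1])
        np.testing.assert_allclose(track.values, d0, atol=1e-12)

    def test_invariant_under_shared_rotation(self, helix20, rng):
        frames = np.stack(
            [
                helix20.coords @ Rotation.random(rng=rng).as_matrix().T
                + rng.normal(0, 4, 3)
                for _ in range(6)
            ]
        )
        track = pair_distance_track(Trajectory(helix20, frames), "3:CA-17:CA")
        assert np.ptp(track.values) < 1e-9

    def test_displacement_event_lowers_window_mean(self):
        # residues 3-5 ramp toward residue 15 by 2 A over frames 60-140
        spec = SyntheticSpec(
            n_residues=20,
            n_frames=200,
            seed=7,
            sigma=0.1,
            displacement_event=DisplacementEvent((3, 5), (0, 0, -2.0), (60, 140)),
            global_motion=True,
            replicates=1,
        )
        cond = generate_condition(spec)
        track = pair_distance_track(cond.replicates[0], "4:CA-15:CA")
        pre = track.values[:60].mean()
        post = track.values[150:].mean()
        base = cond.base.coords
        expected = np.linalg.norm(
            base[3] + [0, 0, -2.0] - base[14]
        ) - np.linalg.norm(base[3] - base[14])
        assert post - pre == pytest.approx(expected, abs=0.05)

    def test_string_pair_and_unresolved_atom(self, helix20):
        traj = Trajectory(helix20, np.stack([helix20.coords] * 2))
        track = pair_distance_track(traj, "1:CA-20:CA")
        assert track.pair_label() == "1:CA-20:CA"
        with pytest.raises(SelectionError):
            pair_distance_track(traj, "1:CB-20:CA")


class TestCompareWindowMeans:
    def test_identical_tracks_zero(self, helix20):
        traj = Trajectory(helix20, np.stack([helix20.coords] * 10))
        a = pair_distance_track(traj, "1:CA-10:CA")
        b = pair_distance_track(traj, "1:CA-10:CA")
        assert compare_window_means(a, b, (0, 9)) == pytest.approx(0)

    def test_constant_offset_recovered(self, helix20):
        traj = Trajectory(helix20, np.stack([helix20.coords] * 10))
        a = pair_distance_track(traj, "1:CA-10:CA")
        b = pair_distance_track(traj, "1:CA-10:CA")
        b.values = b.values - 1.5
        assert compare_window_means(a, b, (0, 9)) == pytest.approx(-1.5)

    def test_window_out_of_range(self, helix20):
        traj = Trajectory(helix20, np.stack([helix20.coords] * 10))
        a = pair_distance_track(traj, "1:CA-10:CA")
        with pytest.raises(WindowError):
            a.window_mean((5, 20))


def cage_spec(n_atoms, spacing=0.2, probe=0.0):
    return PocketSpec(
        lining_selection=Selection(((1, n_atoms),)),
        seed_point=np.zeros(3),
        grid_spacing=spacing,
        probe_radius=probe,
    )


class TestCavityVolume:
    def test_solid_block_with_outside_seed_is_empty(self):
        # close-packed cube of atoms; seed far outside the hull
        grid = np.stack(
            np.meshgrid(*[np.arange(5) * 1.5] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        atoms = tuple(
            Atom(i + 1, "C", "BLK", "A", i + 1, "C", 1.7)
            for i in range(len(grid))
        )
        block = Structure(atoms, grid)
        spec = PocketSpec(
            lining_selection=Selection(((1, len(grid)),)),
            seed_point=np.array([50.0, 50.0, 50.0]),
            grid_spacing=0.5,
            probe_radius=0.0,
        )
        with pytest.warns(UserWarning):
            pv = cavity_volume(block, spec)
        assert pv.volume == 0.0

    def test_sphere_cage_close_to_monte_carlo_oracle(self):
        cage = make_cage_structure(5.5, 1.5, n_atoms=1200)  # cavity radius 4
        pv = cavity_volume(cage, cage_spec(1200, spacing=0.25))
        oracle = mc_cavity_volume(cage.coords, 1.5, n_samples=300_000)
        assert pv.volume == pytest.approx(oracle, rel=0.05)
        assert pv.volume == pytest.approx(4 / 3 * np.pi * 4**3, rel=0.08)

    def test_volume_equals_grid_points_times_voxel(self):
        cage = make_cage_structure(5.5, 1.5, n_atoms=800)
        pv = cavity_volume(cage, cage_spec(800, spacing=0.3))
        assert pv.volume == pytest.approx(pv.grid_points * 0.3**3)

    def test_monotone_nonincreasing_in_probe_radius(self):
        cage = make_cage_structure(5.5, 1.5, n_atoms=800)
        vols = [
            cavity_volume(cage, cage_spec(800, spacing=0.3, probe=p)).volume
            for p in (0.0, 0.7, 1.4)
        ]
        assert vols[0] >= vols[1] >= vols[2]

    def test_rotation_translation_invariance_within_grid_resolution(self, rng):
        cage = make_cage_structure(5.5, 1.5, n_atoms=800)
        spec = cage_spec(800, spacing=0.3)
        v0 = cavity_volume(cage, spec).volume
        rot = Rotation.random(rng=rng).as_matrix()
        shift = np.array([3.3, -1.7, 2.9])
        moved = cage.with_coords(cage.coords @ rot.T + shift)
        spec2 = PocketSpec(
            lining_selection=spec.lining_selection,
            seed_point=spec.seed_point @ rot.T + shift,
            grid_spacing=0.3,
            probe_radius=0.0,
        )
        v1 = cavity_volume(moved, spec2).volume
        surface_bound = 4 * np.pi * 4**2 * 0.3  # surface voxels x spacing^3
        assert abs(v1 - v0) <= surface_bound

    def test_halving_spacing_within_boundary_bound(self):
        cage = make_cage_structure(5.5, 1.5, n_atoms=800)
        v_coarse = cavity_volume(cage, cage_spec(800, spacing=0.5)).volume
        v_fine = cavity_volume(cage, cage_spec(800, spacing=0.25)).volume
        surface_bound = 4 * np.pi * 4**2 * 0.5
        assert abs(v_coarse - v_fine) <= surface_bound

    def test_seed_inside_atom_rejected(self):
        cage = make_cage_structure(5.5, 1.5, n_atoms=400)
        spec = PocketSpec(
            lining_selection=Selection(((1, 400),)),
            seed_point=cage.coords[0],  # dead center of an atom
            grid_spacing=0.3,
            probe_radius=0.0,
        )
        with pytest.raises(SpecValidationError):
            cavity_volume(cage, spec)

    def test_spec_validation(self):
        with pytest.raises(SpecValidationError):
            PocketSpec(Selection(), np.zeros(3), grid_spacing=2.0)
        with pytest.raises(SpecValidationError):
            PocketSpec(Selection(), np.zeros(3), probe_radius=-1.0)
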