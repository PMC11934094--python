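"""Coordinate-space analyses: helices, tilts, membrane metrics, contacts."""

import numpy as np
import pytest

from helixorder import synthetic as syn
from helixorder.exceptions import LeafletError, ParameterError, SelectionError
from helixorder.orientation import p2
from helixorder.trajectory import (
    MolecularFrame,
    Trajectory,
    area_per_lipid,
    assign_helices,
    carbonyl_tilt_angles,
    detect_hbonds,
    dual_cutoff_contacts,
    edge_to_edge_distance,
    ensemble_order_parameter,
    helical_content,
    membrane_thickness,
    read_pdb,
    read_xyz,
    write_pdb,
    write_xyz,
)


def _frame_with_carbonyls(directions):
    """Minimal frame: one C/O pair per direction plus N/CA so residues
    are assignable; helix labels are forced via a canonical backbone."""
    bb = syn.build_ideal_helix(len(directions) + 2)
    frame = syn.chain_to_frame(bb)
    # overwrite O positions of interior residues with the requested dirs
    n_res = len(directions) + 2
    o_block = 3 * n_res
    c_block = 2 * n_res
    for i, d in enumerate(directions, start=1):
        d = np.asarray(d, float)
        frame.coords[o_block + i] = frame.coords[c_block + i] + 1.23 * d / np.linalg.norm(d)
    return frame


class TestAssignHelices:
    def test_ideal_helix_is_one_full_segment(self):
        frame = syn.chain_to_frame(syn.build_ideal_helix(12))
        a = assign_helices(frame)
        assert a.segments == [("A", 1, 12)]
        assert a.n_helix == 12

    def test_extended_strand_has_no_helix(self):
        frame = syn.chain_to_frame(syn.build_chain([(-120.0, 120.0)] * 10))
        a = assign_helices(frame)
        assert a.n_helix == 0 and a.segments == []

    def test_three_residue_run_is_discarded(self):
        pp = [(-120.0, 120.0)] * 3 + [(-57.0, -47.0)] * 3 + [(-120.0, 120.0)] * 3
        a = assign_helices(syn.chain_to_frame(syn.build_chain(pp)))
        assert a.segments == [] and a.n_helix == 0

    def test_four_residue_run_is_kept(self):
        pp = [(-120.0, 120.0)] * 3 + [(-57.0, -47.0)] * 4 + [(-120.0, 120.0)] * 3
        a = assign_helices(syn.chain_to_frame(syn.build_chain(pp)))
        assert len(a.segments) == 1
        chain, start, end = a.segments[0]
        assert end - start + 1 >= 4


class TestHelicalContent:
    def test_all_helix_is_unity_every_frame(self):
        frame = syn.chain_to_frame(syn.build_ideal_helix(20))
        fractions, start, end = helical_content(Trajectory([frame, frame]))
        np.testing.assert_allclose(fractions, 1.0)

    def test_planted_morph_endpoints(self):
        def frame_with(k):
            pp = [(-57.0, -47.0)] * k + [(-120.0, 120.0)] * (100 - k)
            return syn.chain_to_frame(syn.build_chain(pp))

        traj = Trajectory([frame_with(39), frame_with(44), frame_with(49)])
        fractions, start, end = helical_content(traj)
        assert start == pytest.approx(0.39)
        assert end == pytest.approx(0.49)

    def test_single_frame_series_has_length_one(self):
        fractions, _, _ = helical_content(
            Trajectory([syn.chain_to_frame(syn.build_ideal_helix(8))])
        )
        assert fractions.shape == (1,)


class TestCarbonylTilts:
    def test_normal_aligned_carbonyls(self):
        frame = _frame_with_carbonyls([(0, 0, 1)] * 5)
        a = assign_helices(frame)
        angles = carbonyl_tilt_angles(frame, a)
        sel = angles[np.isclose(angles, 0.0, atol=1e-9)]
        assert sel.size >= 5  # interior residues carry the planted dipoles

    def test_cone_at_43_degrees(self):
        d = (np.sin(np.radians(43.0)), 0.0, np.cos(np.radians(43.0)))
        frame = _frame_with_carbonyls([d] * 6)
        angles = carbonyl_tilt_angles(frame, assign_helices(frame))
        assert np.isclose(angles, 43.0, atol=1e-9).sum() >= 6

    def test_in_plane_carbonyl_is_90(self):
        frame = _frame_with_carbonyls([(1, 0, 0)] * 4)
        angles = carbonyl_tilt_angles(frame, assign_helices(frame))
        assert np.isclose(angles, 90.0, atol=1e-9).sum() >= 4


class TestEnsembleOrderParameter:
    def test_planted_43_degree_ensemble_matches_reported_order(self):
        frame, _ = syn.gen_helix_ensemble(
            100, ("delta", 0.0), cone_alpha=43.0, residues_per_helix=12, seed=3
        )
        res = ensemble_order_parameter(frame)
        assert res.theta_deg == pytest.approx(43.0, abs=1e-6)
        assert res.s0 == pytest.approx(0.60, abs=0.05)

    def test_isotropic_axes_are_disordered(self):
        frame, _ = syn.gen_helix_ensemble(
            2000, "isotropic", cone_alpha=36.0, residues_per_helix=12, seed=21
        )
        res = ensemble_order_parameter(frame, alpha=36.0)
        n = 2000 * 12
        assert abs(res.s0) < 3.0 / np.sqrt(n) * 5

    @pytest.mark.parametrize("beta", [20.0, 45.0])
    def test_legendre_closure_recovers_axis_tilt(self, beta):
        frame, truth = syn.gen_helix_ensemble(
            900, ("delta", beta), cone_alpha=36.0, residues_per_helix=12, seed=7
        )
        res = ensemble_order_parameter(frame, alpha=36.0)
        assert res.s0 == pytest.approx(p2(np.cos(np.radians(beta))), abs=0.02)

    def test_single_frame_equals_trajectory_of_it(self):
        frame, _ = syn.gen_helix_ensemble(10, ("delta", 25.0), 36.0, seed=2)
        r1 = ensemble_order_parameter(frame)
        r2 = ensemble_order_parameter(Trajectory([frame]))
        assert r1.s0 == r2.s0


class TestMembraneGeometry:
    def test_planted_thickness_4nm(self, planted_bilayer):
        frame, truth = planted_bilayer
        assert membrane_thickness(frame) == pytest.approx(4.0, abs=1e-9)

    def test_planted_thickness_52nm(self):
        frame, _ = syn.gen_bilayer(nx=8, ny=8, leaflet_sep=5.2, seed=1)
        assert membrane_thickness(frame) == pytest.approx(5.2, abs=1e-9)

    def test_jittered_heads_stay_within_tolerance(self):
        frame, truth = syn.gen_bilayer(nx=18, ny=18, leaflet_sep=4.0, z_jitter=0.05, seed=8)
        assert membrane_thickness(frame) == pytest.approx(4.0, abs=0.02)

    def test_one_sided_headgroups_raise(self):
        frame, _ = syn.gen_bilayer(nx=4, ny=4, leaflet_sep=4.0, seed=0)
        squashed = MolecularFrame(
            frame.atom_name, frame.element, frame.res_id, frame.res_name,
            frame.chain_id, np.column_stack([frame.coords[:, 0], frame.coords[:, 1],
                                             np.zeros(frame.n_atoms)]),
            box=frame.box,
        )
        with pytest.raises(LeafletError):
            membrane_thickness(squashed)

    def test_thickness_invariant_under_translation_and_z_rotation(self, planted_bilayer):
        frame, _ = planted_bilayer
        t0 = membrane_thickness(frame)
        ang = np.radians(30.0)
        rot = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]]
        )
        moved = MolecularFrame(
            frame.atom_name, frame.element, frame.res_id, frame.res_name,
            frame.chain_id, frame.coords @ rot.T + np.array([5.0, -3.0, 12.0]),
            box=frame.box,
        )
        assert membrane_thickness(moved) == pytest.approx(t0, abs=1e-9)

    def test_area_per_lipid_from_box(self):
        frame, truth = syn.gen_bilayer(nx=18, ny=18, apl=0.55, seed=0)
        assert area_per_lipid(frame, truth["lipids_per_leaflet"]) == pytest.approx(
            0.55, abs=1e-9
        )

    def test_area_per_lipid_simulation_box_arithmetic(self):
        frame = MolecularFrame(
            atom_name=np.array(["P", "P"]), element=np.array(["P", "P"]),
            res_id=np.array([1, 2]), res_name=np.array(["LIP", "LIP"]),
            chain_id=np.array(["U", "L"]),
            coords=np.array([[0.0, 0.0, 20.0], [0.0, 0.0, -20.0]]),
            box=np.array([128.6, 128.6, 140.0]),
        )
        assert area_per_lipid(frame, 310) == pytest.approx(0.5335, abs=5e-4)
        with pytest.raises(ParameterError):
            area_per_lipid(frame, 0)


class TestDistances:
    def _two_atom_frame(self, d, box=None):
        return MolecularFrame(
            atom_name=np.array(["O", "N"]), element=np.array(["O", "N"]),
            res_id=np.array([1, 2]), res_name=np.array(["A", "B"]),
            chain_id=np.array(["A", "B"]),
            coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]]), box=box,
        )

    def test_two_atoms_two_angstrom(self):
        frame = self._two_atom_frame(2.0)
        assert edge_to_edge_distance(frame, [0], [1]) == pytest.approx(2.0)

    def test_identical_groups_give_zero(self):
        frame = self._two_atom_frame(2.0)
        assert edge_to_edge_distance(frame, [0, 1], [0, 1]) == 0.0

    def test_minimum_image_wraps(self):
        frame = self._two_atom_frame(9.0, box=np.array([10.0, 10.0, 10.0]))
        assert edge_to_edge_distance(frame, [0], [1]) == pytest.approx(1.0)

    def test_empty_selection_raises(self):
        frame = self._two_atom_frame(2.0)
        with pytest.raises(SelectionError):
            edge_to_edge_distance(frame, [], [1])

    def test_planted_approach_series_ends_at_two_angstrom(self):
        _, d, truth = syn.gen_distance_series(d0=30.0, d_plateau=2.0, t_bind=50.0)
        assert d.min() == pytest.approx(2.0, abs=0.05)
        assert d.min() / 10.0 == pytest.approx(0.2, abs=0.005)  # nm


class TestHbonds:
    def _dha_frame(self, da, deviation_deg):
        # donor O at origin, H along +x; acceptor at distance da from donor,
        # rotated off the D->H axis so the D-H...A deviation equals the target
        h = np.array([0.97, 0.0, 0.0])
        dev = np.radians(deviation_deg)
        # place acceptor such that angle at H between (D-H) and (A-H) is
        # 180 - deviation
        direction = np.array([np.cos(dev), np.sin(dev), 0.0])
        # distance H->A chosen so |D-A| = da
        # solve |h + t*direction| = da
        b = 2 * h @ direction
        c = h @ h - da**2
        t = (-b + np.sqrt(b**2 - 4 * c)) / 2
        acc = h + t * direction
        return MolecularFrame(
            atom_name=np.array(["O", "H", "O"]), element=np.array(["O", "H", "O"]),
            res_id=np.array([1, 1, 2]), res_name=np.array(["DON", "DON", "ACC"]),
            chain_id=np.array(["A", "A", "B"]),
            coords=np.vstack([np.zeros(3), h, acc]),
        )

    def test_good_geometry_is_one_bond(self):
        frame = self._dha_frame(2.9, 10.0)
        bonds = detect_hbonds(frame)
        assert len(bonds) == 1
        assert bonds[0][0] == 0 and bonds[0][2] == 2

    def test_long_distance_rejected(self):
        assert detect_hbonds(self._dha_frame(4.0, 10.0)) == []

    def test_bent_geometry_rejected_by_angle_alone(self):
        assert detect_hbonds(self._dha_frame(3.4, 45.0)) == []

    def test_apolar_frame_gives_empty_list(self):
        frame = MolecularFrame(
            atom_name=np.array(["C1", "C2"]), element=np.array(["C", "C"]),
            res_id=np.array([1, 1]), res_name=np.array(["LIP", "LIP"]),
            chain_id=np.array(["A", "A"]),
            coords=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
        )
        assert detect_hbonds(frame) == []


class TestDualCutoff:
    def test_hand_traced_hysteresis(self):
        series = dual_cutoff_contacts([5, 3, 4.5, 6, 3], r_lower=4.0, r_upper=5.0)
        assert list(series.bound) == [False, True, True, False, True]
        assert series.occupancy == pytest.approx(0.6)

    def test_always_far_gives_zero_occupancy(self):
        series = dual_cutoff_contacts([6, 7, 8], 4.0, 5.5)
        assert series.occupancy == 0.0
        assert series.mean_bound_duration == 0.0

    def test_always_close_gives_full_occupancy(self):
        series = dual_cutoff_contacts([1, 2, 3], 4.0, 5.5)
        assert series.occupancy == 1.0
        assert series.mean_bound_duration == 3.0

    def test_equal_cutoffs_reduce_to_threshold(self):
        d = [5.2, 3.1, 4.9, 6.3, 2.2, 4.4]
        series = dual_cutoff_contacts(d, 4.5, 4.5)
        assert list(series.bound) == [x < 4.5 for x in d]

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ParameterError):
            dual_cutoff_contacts([1.0], 5.0, 4.0)

    def test_hysteresis_suppresses_flicker(self):
        # excursions between the cutoffs do not break the bound state
        d = [3.0, 5.0, 4.8, 5.2, 3.5, 6.0]
        series = dual_cutoff_contacts(d, 4.0, 5.5)
        assert list(series.bound) == [True] * 5 + [False]


class TestFileIO:
    def test_pdb_round_trip(self, tmp_path, planted_bilayer):
        frame, _ = planted_bilayer
        path = tmp_path / "bilayer.pdb"
        write_pdb(path, frame)
        back = read_pdb(path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].coords, frame.coords, atol=1e-2)
        assert membrane_thickness(back[0]) == pytest.approx(4.0, abs=1e-3)

    def test_multi_model_pdb_round_trip(self, tmp_path):
        f1, _ = syn.gen_helix_ensemble(3, ("delta", 10.0), 36.0, seed=1)
        f2 = MolecularFrame(
            f1.atom_name, f1.element, f1.res_id, f1.res_name, f1.chain_id,
            f1.coords + 1.0,
        )
        path = tmp_path / "traj.pdb"
        write_pdb(path, Trajectory([f1, f2]))
        back = read_pdb(path)
        assert len(back) == 2
        np.testing.assert_allclose(
            back[1].coords - back[0].coords, 1.0, atol=1e-2
        )

    def test_xyz_round_trip_with_box(self, tmp_path, planted_bilayer):
        frame, _ = planted_bilayer
        path = tmp_path / "frame.xyz"
        write_xyz(path, frame)
        back = read_xyz(path)
        np.testing.assert_allclose(back[0].coords, frame.coords, atol=1e-5)
        np.testing.assert_allclose(back[0].box, frame.box)
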