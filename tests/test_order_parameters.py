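"""Order parameters: R, Q, RMSD and pair distances against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import chain_frame, extended_chain, make_trajectory
from hairpintse import order_parameters as op
from hairpintse.errors import ConfigurationError, DegenerateGeometryError
from hairpintse.model import NATIVE_PAIRS, AtomRecord, Frame
from hairpintse.trajectory_io import build_reference


def _scale_pairs(frame: Frame, reference, factor_by_pair: dict) -> Frame:
    """Move the second residue of each native pair radially so that the
    instantaneous distance becomes native / ratio."""
    atoms = [AtomRecord(a.residue_index, a.residue_name, a.atom_name, a.coords.copy())
             for a in frame.atoms]
    out = Frame(time=frame.time, atoms=atoms)
    for (i, j), ratio in factor_by_pair.items():
        ci, cj = out.ca(i), out.ca(j)
        direction = (cj - ci) / np.linalg.norm(cj - ci)
        target = reference.native_pair_distances[(i, j)] / ratio
        shift = ci + direction * target - cj
        for a in out.atoms:
            if a.residue_index == j:
                a.coords = a.coords + shift
    return out


class TestR:
    def test_native_distances_give_pair_count(self, native_frame, reference):
        assert op.compute_R(native_frame, reference) == 5.0

    def test_doubled_distances_halve_each_ratio(self, native_frame, reference):
        frame = _scale_pairs(native_frame, reference, {p: 0.5 for p in NATIVE_PAIRS})
        assert op.compute_R(frame, reference) == pytest.approx(2.5, abs=1e-9)

    def test_hand_summed_ratios(self, native_frame, reference):
        ratios = dict(zip(NATIVE_PAIRS, [1.0, 0.8, 0.5, 0.4, 0.25]))
        frame = _scale_pairs(native_frame, reference, ratios)
        assert op.compute_R(frame, reference) == pytest.approx(2.95, abs=1e-9)

    def test_zero_distance_is_degenerate(self, native_frame, reference):
        frame = Frame(native_frame.time,
                      [AtomRecord(a.residue_index, a.residue_name, a.atom_name,
                                  a.coords.copy()) for a in native_frame.atoms])
        ca6 = frame.ca(6)
        for a in frame.atoms:
            if a.residue_index == 10 and a.atom_name == "CA":
                a.coords = ca6.copy()
        with pytest.raises(DegenerateGeometryError):
            op.compute_R(frame, reference)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(-3.0, 3.0), shift=st.floats(-5.0, 5.0))
    def test_rigid_motion_invariance(self, native_frame, reference, angle, shift):
        """R depends only on internal distances."""
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        moved = Frame(0.0, [
            AtomRecord(a.residue_index, a.residue_name, a.atom_name,
                       rot @ a.coords + shift)
            for a in native_frame.atoms
        ])
        assert op.compute_R(moved, reference) == pytest.approx(5.0, abs=1e-9)


class TestQ:
    def test_native_frame_has_all_contacts(self, native_frame, reference):
        assert op.compute_Q(native_frame, reference) == 1.0

    def test_extended_frame_has_none(self, reference):
        frame = chain_frame(extended_chain(), sidechains=True)
        # rename residues to match indices present in the reference
        assert op.compute_Q(frame, reference) == 0.0

    def test_displacing_half_the_contacts_gives_half(self, native_frame, reference):
        """Brute-force recount after pushing half the contact partners away."""
        contacts = sorted(reference.native_contacts)
        broken = contacts[: len(contacts) // 2]
        atoms = [AtomRecord(a.residue_index, a.residue_name, a.atom_name, a.coords.copy())
                 for a in native_frame.atoms]
        frame = Frame(0.0, atoms)
        for (i, j) in broken:
            for a in frame.atoms:
                if a.residue_index == j and a.atom_name != "CA":
                    a.coords = a.coords + np.array([0.0, 0.0, 5.0])
        # independent recount
        expected = 0
        for (i, j) in contacts:
            a = frame.sidechain(i)
            b = frame.sidechain(j)
            d = min(np.linalg.norm(x - y) for x in a for y in b)
            expected += d <= reference.contact_cutoff
        assert expected == len(contacts) - len(broken)
        assert op.compute_Q(frame, reference) == pytest.approx(expected / len(contacts))

    def test_empty_contact_list_is_a_configuration_error(self, native_frame, reference):
        import dataclasses

        empty = dataclasses.replace(reference, native_contacts=set())
        with pytest.raises(ConfigurationError):
            op.compute_Q(native_frame, empty)

    def test_monotone_in_cutoff(self, coordinate_data, reference):
        """Q can only lose contacts as the cutoff shrinks."""
        frame = coordinate_data[0][0].frames[0]
        cutoffs = [0.8, 0.6, 0.55, 0.4, 0.3, 0.2]
        values = [op.compute_Q(frame, reference, contact_cutoff=c) for c in cutoffs]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestRmsd:
    def test_identity_is_zero(self, native_frame, reference):
        assert op.compute_rmsd(native_frame, reference) == pytest.approx(0.0, abs=1e-12)

    def test_superposition_removes_rigid_motion(self, native_frame, reference):
        c, s = np.cos(1.1), np.sin(1.1)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        moved = Frame(0.0, [
            AtomRecord(a.residue_index, a.residue_name, a.atom_name,
                       rot @ a.coords + np.array([1.0, -2.0, 0.5]))
            for a in native_frame.atoms
        ])
        assert op.compute_rmsd(moved, reference) == pytest.approx(0.0, abs=1e-9)

    def test_single_displacement_without_fit_matches_closed_form(self, native_frame, reference):
        bump = np.array([0.3, 0.0, 0.0])
        moved = Frame(0.0, [
            AtomRecord(a.residue_index, a.residue_name, a.atom_name,
                       a.coords + (bump if (a.residue_index, a.atom_name) == (8, "CA") else 0.0))
            for a in native_frame.atoms
        ])
        expected = 0.3 / np.sqrt(15)
        assert op.compute_rmsd(moved, reference, superpose=False) == pytest.approx(
            expected, abs=1e-12
        )

    def test_collinear_points_are_degenerate(self):
        line = chain_frame(extended_chain(5))
        with pytest.raises(DegenerateGeometryError):
            op.kabsch_rmsd(
                np.array([a.coords for a in line.atoms]),
                np.array([a.coords for a in line.atoms]),
            )


class TestDistances:
    def test_single_atom_sidechains(self):
        atoms = [
            AtomRecord(1, "ALA", "CA", np.zeros(3)),
            AtomRecord(1, "ALA", "CB", np.zeros(3)),
            AtomRecord(5, "ALA", "CA", np.array([1.0, 0, 0])),
            AtomRecord(5, "ALA", "CB", np.array([0.0, 0, 0.3])),
        ]
        frame = Frame(0.0, atoms)
        assert op.compute_distance(frame, (1, 5), "sidechain_min") == pytest.approx(0.3)

    def test_min_over_2x2_atom_sets_matches_brute_force(self):
        rng = np.random.default_rng(4)
        a_atoms = rng.normal(size=(2, 3))
        b_atoms = rng.normal(size=(2, 3)) + 1.0
        atoms = [AtomRecord(1, "TRP", "CA", np.zeros(3)),
                 AtomRecord(4, "TYR", "CA", np.ones(3))]
        atoms += [AtomRecord(1, "TRP", f"CD{k + 1}", c) for k, c in enumerate(a_atoms)]
        atoms += [AtomRecord(4, "TYR", f"CE{k + 1}", c) for k, c in enumerate(b_atoms)]
        frame = Frame(0.0, atoms)
        expected = min(np.linalg.norm(x - y) for x in a_atoms for y in b_atoms)
        assert op.compute_distance(frame, (1, 4), "sidechain_min") == pytest.approx(expected)

    def test_calpha_mode_ignores_sidechains(self):
        pts = extended_chain(6)
        frame_a = chain_frame(pts, sidechains=True)
        frame_b = chain_frame(pts, sidechains=True)
        for a in frame_b.atoms:
            if a.atom_name == "CB":
                a.coords = a.coords + 7.0
        d_a = op.compute_distance(frame_a, (1, 6), "calpha")
        d_b = op.compute_distance(frame_b, (1, 6), "calpha")
        assert d_a == d_b

    def test_series_matches_per_frame_computation(self, coordinate_data):
        trajs, _ = coordinate_data
        traj = make_trajectory(trajs[0].frames[:20], dt=10.0)
        series = op.compute_distance_series(traj, (6, 9), "calpha")
        per_frame = [op.compute_distance(f, (6, 9), "calpha") for f in traj.frames]
        np.testing.assert_allclose(series.values, per_frame, atol=1e-12)


def test_vectorized_series_matches_per_frame(coordinate_data):
    """The trajectory-level fast path agrees with the frame-level definitions."""
    trajs, ref = coordinate_data
    traj = make_trajectory(trajs[0].frames[:25], dt=10.0)
    series = op.compute_series(traj, ref, with_rmsd=True)
    for k in (0, 7, 24):
        frame = traj.frames[k]
        assert series.data["R"][k] == pytest.approx(op.compute_R(frame, ref), abs=1e-9)
        assert series.data["Q"][k] == pytest.approx(op.compute_Q(frame, ref), abs=1e-12)
        assert series.data["RMSD"][k] == pytest.approx(op.compute_rmsd(frame, ref), abs=1e-9)
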