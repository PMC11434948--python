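"""Core model invariants and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pecomplex.io import (
    ParseError,
    read_structure,
    read_trajectory,
    write_structure,
    write_trajectory,
)
from pecomplex.model import (
    AnalysisWindow,
    Frame,
    MoleculeClass,
    Trajectory,
    classify_residue,
    minimum_image_distance,
)


def brute_force_min_image(p1, p2, box):
    """Minimum distance over the 27 periodic images (independent oracle)."""
    best = np.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                shift = np.array([sx, sy, sz]) * box
                best = min(best, float(np.linalg.norm(p1 - (p2 + shift))))
    return best


class TestMinimumImage:
    def test_wrap_around(self):
        assert minimum_image_distance(
            np.zeros(3), np.array([4.9, 0, 0]), np.array([5.0, 5, 5])
        ) == pytest.approx(0.1)

    def test_identity(self):
        p = np.array([1.2, 3.4, 0.5])
        assert minimum_image_distance(p, p, np.array([5.0, 5, 5])) == 0.0

    def test_matches_image_enumeration(self):
        rng = np.random.default_rng(7)
        box = np.array([4.0, 5.5, 3.2])
        for _ in range(1000):
            p1, p2 = rng.uniform(0, 1, size=(2, 3)) * box
            assert minimum_image_distance(p1, p2, box) == pytest.approx(
                brute_force_min_image(p1, p2, box), abs=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_integer_box_translation_leaves_distances_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        box = rng.uniform(2, 6, size=3)
        p1, p2 = rng.uniform(0, 10, size=(2, 3))
        shift = rng.integers(-3, 4, size=3) * box
        assert minimum_image_distance(p1 + shift, p2, box) == pytest.approx(
            minimum_image_distance(p1, p2, box), abs=1e-9
        )

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(1)
        box = np.array([3.0, 3.0, 3.0])
        for _ in range(50):
            p1, p2 = rng.uniform(0, 3, size=(2, 3))
            d12 = minimum_image_distance(p1, p2, box)
            assert d12 == pytest.approx(minimum_image_distance(p2, p1, box))
            assert d12 <= np.linalg.norm(box / 2) + 1e-12


class TestStructureIO:
    PDB_5ATOM = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.458  10.000  10.000  1.00  0.00           C
ATOM      3  C   ALA A   1      12.000  11.400  10.000  1.00  0.00           C
ATOM      4  O   ALA A   1      13.200  11.600  10.000  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.000   8.800  10.000  1.00  0.00           C
END
"""

    def test_hand_written_pdb(self, tmp_path):
        path = tmp_path / "five.pdb"
        path.write_text(self.PDB_5ATOM)
        top, frame = read_structure(path)
        assert top.n_atoms == 5
        assert top.n_residues == 1
        assert list(top.names) == ["N", "CA", "C", "O", "CB"]
        assert frame.box == pytest.approx([5.0, 5.0, 5.0])
        assert frame.coordinates[0] == pytest.approx([1.0, 1.0, 1.0])

    def test_pdb_round_trip(self, tmp_path, mixture_system):
        top, traj = mixture_system
        path = tmp_path / "sys.pdb"
        write_structure(path, top, traj.frames[0])
        top2, frame2 = read_structure(path)
        assert top2.n_atoms == top.n_atoms
        assert top2.n_residues == top.n_residues
        assert list(top2.names) == list(top.names)
        assert list(top2.residue_types) == list(top.residue_types)
        # PDB stores 3 decimals in Å -> 1e-4 nm
        assert np.abs(frame2.coordinates - traj.frames[0].coordinates).max() < 1.1e-4

    def test_pdb_read_by_independent_parser(self, tmp_path, mixture_system):
        biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
        top, traj = mixture_system
        path = tmp_path / "sys.pdb"
        write_structure(path, top, traj.frames[0])
        arr = biotite_pdb.PDBFile.read(str(path)).get_structure(model=1)
        assert arr.array_length() == top.n_atoms
        assert np.abs(arr.coord / 10.0 - traj.frames[0].coordinates).max() < 1.1e-4

    def test_gro_round_trip_and_box(self, tmp_path, mixture_system):
        top, traj = mixture_system
        path = tmp_path / "sys.gro"
        write_structure(path, top, traj.frames[0])
        top2, frame2 = read_structure(path)
        assert top2.n_atoms == top.n_atoms
        assert frame2.box == pytest.approx(traj.frames[0].box, abs=1e-5)
        # GRO stores 3 decimals in nm
        assert np.abs(frame2.coordinates - traj.frames[0].coordinates).max() < 1.1e-3

    def test_gro_box_line(self, tmp_path):
        path = tmp_path / "two.gro"
        path.write_text(
            "toy t= 0.0\n    2\n    1ALA      N    1   1.000   1.000   1.000\n"
            "    1ALA     CA    2   1.146   1.000   1.000\n"
            "   5.00000   5.00000   5.00000\n"
        )
        _, frame = read_structure(path)
        assert frame.box == pytest.approx([5.0, 5.0, 5.0])

    def test_gro_read_by_independent_parser(self, tmp_path, mixture_system):
        mda = pytest.importorskip("MDAnalysis")
        top, traj = mixture_system
        path = tmp_path / "sys.gro"
        write_structure(path, top, traj.frames[0])
        u = mda.Universe(str(path))
        assert len(u.atoms) == top.n_atoms
        assert np.abs(u.atoms.positions / 10.0 - traj.frames[0].coordinates).max() < 1.1e-3

    def test_malformed_pdb_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  N   ALA A   1      bad coords here\n")
        with pytest.raises(ParseError, match="bad.pdb:1"):
            read_structure(path)

    def test_unknown_residue_code_warns(self, tmp_path):
        path = tmp_path / "odd.pdb"
        path.write_text(
            "ATOM      1  C   XYZ A   1      10.000  10.000  10.000  1.00  0.00           C\n"
        )
        with pytest.warns(UserWarning, match="XYZ"):
            top, _ = read_structure(path)
        assert top.molecules[0].klass == MoleculeClass.OTHER


class TestTrajectoryIO:
    def test_three_frame_xyz(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text(
            "".join(
                f"2\nbox=5.0,5.0,5.0 time={k}.0\nC 1.0 1.0 1.0\nC 2.0 2.0 2.0\n"
                for k in range(3)
            )
        )
        traj = read_trajectory(path)
        assert traj.n_frames == 3
        assert traj.frames[1].time == 1.0
        assert traj.frames[0].box == pytest.approx([5.0, 5.0, 5.0])

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.xyz"
        path.write_text("")
        with pytest.raises(ParseError):
            read_trajectory(path)

    def test_inconsistent_atom_count_names_frame(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\nbox=5,5,5\nC 1 1 1\nC 2 2 2\n1\nbox=5,5,5\nC 1 1 1\n")
        with pytest.raises(ParseError, match="frame 1"):
            read_trajectory(path)

    @pytest.mark.parametrize("fmt", ["xyz", "gro"])
    def test_round_trip(self, tmp_path, mixture_system, fmt):
        top, traj = mixture_system
        path = tmp_path / f"t.{fmt}"
        write_trajectory(path, traj)
        back = read_trajectory(path, topology=top if fmt == "xyz" else None)
        assert back.n_frames == traj.n_frames
        tol = 1.1e-6 if fmt == "xyz" else 1.1e-3  # declared precision per format
        assert np.abs(back.coordinate_array() - traj.coordinate_array()).max() < tol
        assert [f.time for f in back] == pytest.approx([f.time for f in traj])


class TestModelValidation:
    def test_trajectory_rejects_mismatched_frames(self, mixture_system):
        top, traj = mixture_system
        bad = Frame(np.zeros((3, 3)) + 1.0, traj.frames[0].box)
        with pytest.raises(ValueError, match="atoms"):
            Trajectory(top, [bad])

    def test_frame_rejects_bad_box(self):
        with pytest.raises(ValueError, match="box"):
            Frame(np.zeros((2, 3)), np.array([1.0, -1.0, 1.0]))

    def test_window_validation(self):
        with pytest.raises(ValueError):
            AnalysisWindow(0.8, 0.2)
        assert list(AnalysisWindow(0.5, 1.0).frame_indices(10)) == [5, 6, 7, 8, 9]

    def test_classify_residue(self):
        assert classify_residue("ARG") == MoleculeClass.PROTEIN
        assert classify_residue("AAD") == MoleculeClass.POLYELECTROLYTE
        assert classify_residue("HOH") == MoleculeClass.WATER
        assert classify_residue("NA") == MoleculeClass.CATION
        assert classify_residue("CL") == MoleculeClass.ANION
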