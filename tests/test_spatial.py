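"""COM grouping, RDF normalization, and Shrake-Rupley SASA closed forms."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pecomplex.model import (
    AnalysisWindow,
    Atom,
    Frame,
    Molecule,
    MoleculeClass,
    Residue,
    Topology,
    Trajectory,
)
from pecomplex.spatial import (
    golden_spiral_points,
    group_centers,
    rdf,
    residue_groups,
    sasa,
    sasa_timeseries,
)
from pecomplex.synthetic import ideal_gas


def bead_topology(n, masses=None):
    masses = masses if masses is not None else [12.011] * n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Topology(
            [Atom(i, "X", "C", masses[i], residue_index=i) for i in range(n)],
            [Residue(i, "UNK", i) for i in range(n)],
            [Molecule(i, MoleculeClass.OTHER) for i in range(n)],
        )


class TestGroupCenters:
    BOX = np.array([5.0, 5.0, 5.0])

    def test_midpoint(self):
        top = bead_topology(2, [1.0, 1.0])
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]), self.BOX)
        centers = group_centers(frame, top, [np.array([0, 1])])
        assert centers[0] == pytest.approx([0.5, 0.0, 0.0])

    def test_straddling_boundary_wraps(self):
        top = bead_topology(2, [1.0, 1.0])
        frame = Frame(np.array([[0.1, 0, 0], [4.9, 0, 0]]), self.BOX)
        centers = group_centers(frame, top, [np.array([0, 1])])
        assert centers[0][0] == pytest.approx(0.0, abs=1e-12)

    def test_mass_weighting(self):
        top = bead_topology(2, [1.0, 3.0])
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]), self.BOX)
        centers = group_centers(frame, top, [np.array([0, 1])])
        assert centers[0][0] == pytest.approx(0.75)

    def test_empty_group_rejected(self):
        top = bead_topology(1)
        frame = Frame(np.zeros((1, 3)), self.BOX)
        with pytest.raises(ValueError, match="empty"):
            group_centers(frame, top, [np.array([], dtype=int)])


def brute_force_rdf_counts(traj, groups_a, groups_b, edges, same):
    """All-pairs histogram oracle for a small system."""
    counts = np.zeros(len(edges) - 1)
    for frame in traj:
        ca = group_centers(frame, traj.topology, groups_a)
        cb = group_centers(frame, traj.topology, groups_b)
        for i in range(len(groups_a)):
            for j in range(len(groups_b)):
                if same and i == j:
                    continue
                d = ca[i] - cb[j]
                d -= frame.box * np.round(d / frame.box)
                r = np.linalg.norm(d)
                k = int(r // (edges[1] - edges[0]))
                if k < len(counts):
                    counts[k] += 1
    return counts


class TestRdf:
    def test_matches_brute_force_bins(self):
        traj = ideal_gas(20, (4.0, 4.0, 4.0), 5, seed=21)
        groups = [np.array([i]) for i in range(20)]
        result = rdf(traj, groups, groups, bin_width=0.1, window=AnalysisWindow(0.0, 1.0))
        edges = np.arange(len(result.counts) + 1) * 0.1
        oracle = brute_force_rdf_counts(traj, groups, groups, edges, same=True)
        assert np.array_equal(result.counts, oracle)

    def test_symmetric_in_group_order(self, mixture_system):
        top, traj = mixture_system
        ga = residue_groups(top, MoleculeClass.PROTEIN)
        gb = residue_groups(top, MoleculeClass.POLYELECTROLYTE)
        ab = rdf(traj, ga, gb, bin_width=0.05)
        ba = rdf(traj, gb, ga, bin_width=0.05)
        assert np.array_equal(ab.counts, ba.counts)
        assert ab.g == pytest.approx(ba.g)

    def test_hard_core_region_is_empty(self, contact_system):
        top, traj = contact_system
        groups = residue_groups(top, MoleculeClass.PROTEIN)
        result = rdf(traj, groups, groups, bin_width=0.01, window=AnalysisWindow(0.0, 1.0))
        # residue COMs are at least a backbone step apart
        assert result.g[result.bin_centers < 0.1].sum() == 0.0

    def test_counting_identity(self):
        traj = ideal_gas(30, (4.0, 4.0, 4.0), 10, seed=22)
        groups = [np.array([i]) for i in range(30)]
        result = rdf(traj, groups, groups, bin_width=0.05, window=AnalysisWindow(0.0, 1.0))
        # integral of rho_B g(r) 4 pi r^2 dr == mean neighbor count within r_max
        shell = 4.0 / 3.0 * np.pi * (
            (result.bin_centers + 0.025) ** 3 - (result.bin_centers - 0.025) ** 3
        )
        rho = 29 / 64.0
        integral = float((rho * result.g * shell).sum())
        mean_neighbors = result.counts.sum() / (10 * 30)
        assert integral == pytest.approx(mean_neighbors, rel=1e-9)

    def test_r_max_above_half_box_rejected(self):
        traj = ideal_gas(10, (4.0, 4.0, 4.0), 2, seed=23)
        groups = [np.array([i]) for i in range(10)]
        with pytest.raises(ValueError, match="half"):
            rdf(traj, groups, groups, bin_width=0.1, r_max=2.5)


class TestSasa:
    BOX = np.array([10.0, 10.0, 10.0])

    def test_isolated_sphere(self):
        top = bead_topology(1)
        frame = Frame(np.array([[5.0, 5.0, 5.0]]), self.BOX)
        area = sasa(frame, top, np.array([0]), probe_radius=0.14, radii={"C": 0.2})
        assert area == pytest.approx(4 * np.pi * 0.34**2, rel=1e-6)

    def test_two_sphere_closed_form(self):
        # expanded radius R = 0.2 nm at separation d = 0.2 nm:
        # exposed area per sphere = 4 pi R^2 - 2 pi R h, h = R - d/2
        top = bead_topology(2)
        frame = Frame(np.array([[5.0, 5, 5], [5.2, 5, 5]]), self.BOX)
        area = sasa(frame, top, np.array([0, 1]), probe_radius=0.14, radii={"C": 0.06})
        expected = 2 * (4 * np.pi * 0.2**2 - 2 * np.pi * 0.2 * 0.1)
        assert area == pytest.approx(expected, rel=0.01)

    def test_quadrature_convergence(self):
        top = bead_topology(2)
        frame = Frame(np.array([[5.0, 5, 5], [5.2, 5, 5]]), self.BOX)
        a960 = sasa(frame, top, np.array([0, 1]), n_sphere_points=960, radii={"C": 0.06})
        a1920 = sasa(frame, top, np.array([0, 1]), n_sphere_points=1920, radii={"C": 0.06})
        assert abs(a1920 - a960) / a960 < 0.005

    def test_buried_sphere_is_zero(self):
        small_in_big = Frame(np.array([[5.0, 5, 5], [5.0, 5, 5]]), self.BOX)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top2 = Topology(
                [
                    Atom(0, "X", "C", 12.0, residue_index=0),
                    Atom(1, "Y", "N", 14.0, residue_index=1),
                ],
                [Residue(0, "UNK", 0), Residue(1, "UNK", 1)],
                [Molecule(0, MoleculeClass.OTHER), Molecule(1, MoleculeClass.OTHER)],
            )
        area = sasa(
            small_in_big, top2, np.array([0, 1]), probe_radius=0.0, radii={"C": 0.05, "N": 0.3}
        )
        # the small sphere contributes nothing; total equals the big sphere alone
        assert area == pytest.approx(4 * np.pi * 0.3**2, rel=1e-6)

    def test_rigid_motion_invariance(self, mixture_system):
        top, traj = mixture_system
        group = top.class_atom_indices(MoleculeClass.PROTEIN)
        frame = traj.frames[0]
        base = sasa(frame, top, group)
        translated = Frame(frame.coordinates + np.array([3.0, -1.0, 2.0]), frame.box)
        assert sasa(translated, top, group) == pytest.approx(base, rel=1e-12)
        rot = Rotation.from_euler("xyz", [33, -20, 64], degrees=True).as_matrix()
        rotated = Frame(frame.coordinates @ rot.T + np.array([3.0, -1.0, 2.0]), frame.box)
        # rotation moves the fixed quadrature grid relative to the molecule:
        # invariant only up to the quadrature error at 960 points
        assert sasa(rotated, top, group) == pytest.approx(base, rel=5e-3)

    def test_missing_radius_names_element(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top = Topology(
                [Atom(0, "X", "XE", 131.0, residue_index=0)],
                [Residue(0, "UNK", 0)],
                [Molecule(0, MoleculeClass.OTHER)],
            )
        frame = Frame(np.array([[5.0, 5, 5]]), self.BOX)
        with pytest.raises(ValueError, match="XE"):
            sasa(frame, top, np.array([0]))

    def test_timeseries_stats(self, mixture_system):
        top, traj = mixture_system
        group = top.class_atom_indices(MoleculeClass.POLYELECTROLYTE)
        result = sasa_timeseries(traj, group, window=AnalysisWindow(0.5, 1.0), n_sphere_points=240)
        assert result.per_frame.shape == result.frame_indices.shape
        assert result.mean == pytest.approx(result.per_frame.mean())
        assert (result.per_frame > 0).all()


def test_golden_spiral_points_are_unit_and_spread():
    pts = golden_spiral_points(500)
    assert np.linalg.norm(pts, axis=1) == pytest.approx(np.ones(500))
    # quasi-uniformity: octant occupancy within 20% of the ideal share
    octants = (pts > 0).astype(int) @ np.array([1, 2, 4])
    counts = np.bincount(octants, minlength=8)
    assert counts.min() > 0.8 * 500 / 8
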