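"""Non-bonded pair energies: analytic anchors, mixing rules, brute-force
equivalence, symmetry, and extensivity."""

import numpy as np
import pytest

from pecomplex.accounting import COULOMB_CONSTANT_KJ_NM
from pecomplex.energetics import class_pair_energy, coulomb_pair_energy, lj_pair_energy
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
from pecomplex.synthetic import SyntheticSpec, build_system


class TestPairFormulas:
    def test_lj_vanishes_at_sigma(self):
        # sigma_ij = 0.4 via Lorentz mixing
        assert lj_pair_energy(0.4, 0.3, 0.5, 1.0, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_is_minus_epsilon(self):
        # eps_ij = sqrt(1*4) = 2 at r = 2^(1/6) sigma_ij
        r_min = 2 ** (1 / 6) * 0.4
        assert lj_pair_energy(r_min, 0.3, 0.5, 1.0, 4.0) == pytest.approx(-2.0)

    def test_lj_truncated_beyond_cutoff(self):
        assert lj_pair_energy(1.2, 0.3, 0.5, 1.0, 4.0, cutoff=1.0) == 0.0

    def test_coulomb_at_half_nm(self):
        assert coulomb_pair_energy(0.5, 1.0, 1.0) == pytest.approx(277.87, abs=0.01)

    def test_coulomb_antisymmetric_in_charge(self):
        assert coulomb_pair_energy(0.5, 1.0, -1.0) == -coulomb_pair_energy(0.5, 1.0, 1.0)

    def test_coulomb_truncated(self):
        assert coulomb_pair_energy(1.2, 1.0, 1.0, cutoff=1.0) == 0.0

    @pytest.mark.parametrize("func", [lj_pair_energy, coulomb_pair_energy])
    def test_overlap_rejected(self, func):
        with pytest.raises(ValueError):
            if func is lj_pair_energy:
                func(0.0, 0.3, 0.3, 1.0, 1.0)
            else:
                func(0.0, 1.0, 1.0)


def ion_pair_system(separation=0.5):
    atoms = [
        Atom(0, "NA", "NA", 22.99, partial_charge=1.0, lj_sigma=0.23, lj_epsilon=0.45, residue_index=0),
        Atom(1, "CL", "CL", 35.45, partial_charge=-1.0, lj_sigma=0.43, lj_epsilon=0.45, residue_index=1),
    ]
    residues = [Residue(0, "NA", 0), Residue(1, "CL", 1)]
    molecules = [Molecule(0, MoleculeClass.CATION), Molecule(1, MoleculeClass.ANION)]
    top = Topology(atoms, residues, molecules)
    coords = np.array([[2.0, 2.0, 2.0], [2.0 + separation, 2.0, 2.0]])
    return top, Trajectory(top, [Frame(coords, np.array([6.0, 6.0, 6.0]))])


def brute_force_class_energy(frame, top, ia, ib, same, exclusions, cutoff=1.0):
    pos = frame.wrapped()
    e_c = e_lj = 0.0
    seen = set()
    for i in ia:
        for j in ib:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if same:
                if key in seen or key in exclusions:
                    continue
                seen.add(key)
            d = pos[i] - pos[j]
            d -= frame.box * np.round(d / frame.box)
            r = float(np.linalg.norm(d))
            if r <= cutoff:
                e_c += COULOMB_CONSTANT_KJ_NM * top.charges[i] * top.charges[j] / r
                sig = 0.5 * (top.lj_sigma[i] + top.lj_sigma[j])
                eps = np.sqrt(top.lj_epsilon[i] * top.lj_epsilon[j])
                x6 = (sig / r) ** 6
                e_lj += 4 * eps * (x6 * x6 - x6)
    return e_c, e_lj


class TestClassPairEnergy:
    def test_isolated_ion_pair(self):
        top, traj = ion_pair_system(0.5)
        dec = class_pair_energy(
            traj, MoleculeClass.CATION, MoleculeClass.ANION, window=AnalysisWindow(0.0, 1.0)
        )
        assert dec.mean["coulomb"] == pytest.approx(-277.87, abs=0.01)
        assert dec.mean["lj"] == pytest.approx(lj_pair_energy(0.5, 0.23, 0.43, 0.45, 0.45))

    def test_zero_charge_class_has_zero_coulomb(self):
        top, traj = build_system(
            SyntheticSpec(
                n_protein_residues=5,
                ss_plan="C" * 5,
                n_chains=1,
                monomers_per_chain=4,
                deprotonated_fraction=0.0,  # fully protonated: neutral polymer
                planted_contacts=(("ALA", 0.3),),
                seed=61,
            )
        )
        dec = class_pair_energy(
            traj,
            MoleculeClass.PROTEIN,
            MoleculeClass.POLYELECTROLYTE,
            window=AnalysisWindow(0.0, 1.0),
        )
        assert dec.mean["coulomb"] == 0.0
        assert dec.mean["lj"] != 0.0

    def test_matches_brute_force_cross_class(self):
        top, traj = build_system(
            SyntheticSpec(
                n_protein_residues=4,
                ss_plan="CCCC",
                protein_net_charge=2,
                n_chains=1,
                monomers_per_chain=4,
                planted_contacts=(("ALA", 0.35),),
                seed=62,
                n_frames=3,
                jitter_sigma=0.02,
            )
        )
        ia = top.class_atom_indices(MoleculeClass.PROTEIN)
        ib = top.class_atom_indices(MoleculeClass.POLYELECTROLYTE)
        dec = class_pair_energy(
            traj, MoleculeClass.PROTEIN, MoleculeClass.POLYELECTROLYTE, window=AnalysisWindow(0.0, 1.0)
        )
        for row, k in enumerate(dec.per_frame.index):
            e_c, e_lj = brute_force_class_energy(traj.frames[k], top, ia, ib, False, set())
            assert dec.per_frame.iloc[row]["coulomb"] == pytest.approx(e_c, rel=1e-10, abs=1e-10)
            assert dec.per_frame.iloc[row]["lj"] == pytest.approx(e_lj, rel=1e-10, abs=1e-10)

    def test_matches_brute_force_self_class_with_exclusions(self, helix_system):
        top, traj = helix_system
        ia = top.class_atom_indices(MoleculeClass.PROTEIN)
        exclusions = top.bonded_exclusions(2)
        dec = class_pair_energy(
            traj, MoleculeClass.PROTEIN, MoleculeClass.PROTEIN, window=AnalysisWindow(0.0, 0.5)
        )
        for row, k in enumerate(dec.per_frame.index):
            e_c, e_lj = brute_force_class_energy(traj.frames[k], top, ia, ia, True, exclusions)
            assert dec.per_frame.iloc[row]["coulomb"] == pytest.approx(e_c, rel=1e-10, abs=1e-10)
            assert dec.per_frame.iloc[row]["lj"] == pytest.approx(e_lj, rel=1e-10, abs=1e-10)

    def test_symmetric_in_class_order(self, mixture_system):
        top, traj = mixture_system
        ab = class_pair_energy(traj, MoleculeClass.PROTEIN, MoleculeClass.POLYELECTROLYTE)
        ba = class_pair_energy(traj, MoleculeClass.POLYELECTROLYTE, MoleculeClass.PROTEIN)
        assert ab.mean["coulomb"] == pytest.approx(ba.mean["coulomb"])
        assert ab.mean["lj"] == pytest.approx(ba.mean["lj"])

    def test_extensivity_under_system_duplication(self):
        top, traj = ion_pair_system(0.5)
        frame = traj.frames[0]
        # duplicate the ion pair one box-length away in a doubled box
        atoms = []
        for copy in range(2):
            for a in top.atoms:
                atoms.append(
                    Atom(
                        index=copy * 2 + a.index,
                        name=a.name,
                        element=a.element,
                        mass=a.mass,
                        partial_charge=a.partial_charge,
                        lj_sigma=a.lj_sigma,
                        lj_epsilon=a.lj_epsilon,
                        residue_index=copy * 2 + a.residue_index,
                    )
                )
        residues = [
            Residue(0, "NA", 0),
            Residue(1, "CL", 1),
            Residue(2, "NA", 2),
            Residue(3, "CL", 3),
        ]
        molecules = [
            Molecule(0, MoleculeClass.CATION),
            Molecule(1, MoleculeClass.ANION),
            Molecule(2, MoleculeClass.CATION),
            Molecule(3, MoleculeClass.ANION),
        ]
        top2 = Topology(atoms, residues, molecules)
        coords = np.vstack([frame.coordinates, frame.coordinates + np.array([6.0, 0, 0])])
        traj2 = Trajectory(top2, [Frame(coords, np.array([12.0, 6.0, 6.0]))])
        single = class_pair_energy(
            traj, MoleculeClass.CATION, MoleculeClass.ANION, window=AnalysisWindow(0.0, 1.0)
        )
        double = class_pair_energy(
            traj2, MoleculeClass.CATION, MoleculeClass.ANION, window=AnalysisWindow(0.0, 1.0)
        )
        assert double.mean["coulomb"] == pytest.approx(2 * single.mean["coulomb"])
        assert double.mean["lj"] == pytest.approx(2 * single.mean["lj"])

    def test_missing_class_rejected(self, helix_system):
        top, traj = helix_system
        with pytest.raises(ValueError, match="no atoms"):
            class_pair_energy(traj, MoleculeClass.PROTEIN, MoleculeClass.WATER)
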