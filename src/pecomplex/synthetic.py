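"""Seeded generator of toy protein/polyelectrolyte/solvent systems.

Builds an all-atom-like periodic system mirroring the composition of a
lysozyme/poly(acrylic acid) solution: one polypeptide with backbone
N, H, Cα, C, O atoms plus a pseudo side-chain carbon per residue, linear
acrylic-acid chains with per-monomer carboxyl groups (configurable
deprotonation pattern, every second monomer at 50%), monovalent
counterions added to exact neutrality, and optional water beads.

Secondary structure, protein-polymer contacts, and hydrogen bonds can be
*planted* with ideal geometry, giving ground truth that the downstream
classifiers must recover.  Dynamics are emulated as uncorrelated Gaussian
jitter around the constructed frame — sufficient to exercise averaging,
fluctuation, and recovery statistics, with no pretension of physical
kinetics.

The same seed always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import yaml

from .accounting import ChargeSpec, counterions_for_neutrality
from .geometry import build_backbone
from .model import (
    Atom,
    Frame,
    Molecule,
    MoleculeClass,
    Residue,
    Topology,
    Trajectory,
    AMINO_ACIDS,
    ELEMENT_MASSES,
)

__all__ = ["PlantedHBond", "SyntheticSpec", "build_system", "ideal_gas"]

# Pairing constants for antiparallel strand placement: rotate the partner
# 180 degrees about the amide-H face axis and offset it 0.42 nm along it;
# this produces mutual backbone H-bonds on every paired residue.
_STRAND_OFFSET_NM = 0.42

_DEFAULT_PALETTE = (
    "ALA GLY SER THR LEU ILE VAL ASN GLN ARG LYS HIS ASP GLU CYS MET PHE TYR TRP PRO".split()
)

_LJ_HEAVY = (0.32, 0.50)  # sigma nm, epsilon kJ/mol
_LJ_H = (0.11, 0.065)
_WATER_MASS = 18.015


@dataclass(frozen=True)
class PlantedHBond:
    """A hydrogen bond to construct with ideal geometry (r_DA = 3.0 Å, HDA = 0°).

    ``donor`` / ``acceptor`` name molecule classes ("protein",
    "polyelectrolyte", "water"); for protein sites an optional residue type
    selects where the donor/acceptor group is grafted.
    """

    donor: str
    acceptor: str
    donor_residue_type: str | None = None
    acceptor_residue_type: str | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic system; all lengths nm, times ns."""

    n_protein_residues: int = 0
    ss_plan: str | None = None
    sequence: tuple[str, ...] | None = None
    protein_net_charge: int = 0
    n_chains: int = 0
    monomers_per_chain: int = 40
    deprotonated_fraction: float = 0.5
    n_waters: int = 0
    water_sites: int = 1
    box: tuple[float, float, float] | None = None
    planted_contacts: tuple[tuple[str, float], ...] = ()
    planted_hbonds: tuple[PlantedHBond, ...] = ()
    seed: int = 0
    n_frames: int = 1
    jitter_sigma: float = 0.0
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deprotonated_fraction <= 1.0:
            raise ValueError(f"deprotonated_fraction must lie in [0,1], got {self.deprotonated_fraction}")
        if self.ss_plan is not None and len(self.ss_plan) != self.n_protein_residues:
            raise ValueError(
                f"ss_plan length {len(self.ss_plan)} != n_protein_residues {self.n_protein_residues}"
            )
        if self.sequence is not None and len(self.sequence) != self.n_protein_residues:
            raise ValueError("sequence length must equal n_protein_residues")
        if self.water_sites not in (1, 3):
            raise ValueError("water_sites must be 1 (bead) or 3 (explicit H)")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    def resolved_plan(self) -> str:
        return self.ss_plan if self.ss_plan is not None else "C" * self.n_protein_residues

    def resolved_sequence(self) -> list[str]:
        if self.sequence is not None:
            seq = list(self.sequence)
        else:
            seq = [
                _DEFAULT_PALETTE[i % len(_DEFAULT_PALETTE)] for i in range(self.n_protein_residues)
            ]
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"unknown residue codes in sequence: {sorted(bad)}")
        return seq

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["planted_hbonds"] = [asdict(h) for h in self.planted_hbonds]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["planted_hbonds"] = tuple(
            PlantedHBond(**h) for h in (data.get("planted_hbonds") or ())
        )
        for key in ("sequence", "box"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        data["planted_contacts"] = tuple(
            (t, float(d)) for t, d in (data.get("planted_contacts") or ())
        )
        return cls(**data)


class _Builder:
    """Accumulates atoms/residues/molecules, then emits a residue-contiguous Topology."""

    def __init__(self) -> None:
        self.molecule_classes: list[MoleculeClass] = []
        self.residue_types: list[str] = []
        self.residue_molecule: list[int] = []
        self.atom_rows: list[tuple] = []  # (residue, name, element, mass, charge, sigma, eps)
        self.positions: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []

    def new_molecule(self, klass: MoleculeClass) -> int:
        self.molecule_classes.append(klass)
        return len(self.molecule_classes) - 1

    def new_residue(self, type_code: str, molecule: int) -> int:
        self.residue_types.append(type_code)
        self.residue_molecule.append(molecule)
        return len(self.residue_types) - 1

    def add_atom(
        self,
        residue: int,
        name: str,
        element: str,
        position: np.ndarray,
        charge: float = 0.0,
        lj: tuple[float, float] | None = None,
        mass: float | None = None,
    ) -> int:
        if lj is None:
            lj = _LJ_H if element == "H" else _LJ_HEAVY
        if mass is None:
            mass = ELEMENT_MASSES[element.upper()]
        self.atom_rows.append((residue, name, element, mass, charge, lj[0], lj[1]))
        self.positions.append(np.asarray(position, dtype=float))
        return len(self.atom_rows) - 1

    def add_bond(self, i: int, j: int) -> None:
        self.bonds.append((min(i, j), max(i, j)))

    def total_charge(self) -> float:
        return sum(r[4] for r in self.atom_rows)

    def finish(self, box: np.ndarray) -> tuple[Topology, np.ndarray]:
        # stable reorder: group atoms by residue so serialization round-trips
        order = sorted(range(len(self.atom_rows)), key=lambda k: (self.atom_rows[k][0], k))
        remap = {old: new for new, old in enumerate(order)}
        atoms = []
        for new, old in enumerate(order):
            res, name, element, mass, charge, sig, eps = self.atom_rows[old]
            atoms.append(
                Atom(
                    index=new,
                    name=name,
                    element=element,
                    mass=mass,
                    partial_charge=charge,
                    lj_sigma=sig,
                    lj_epsilon=eps,
                    residue_index=res,
                )
            )
        residues = [
            Residue(index=k, type_code=t, molecule_index=m)
            for k, (t, m) in enumerate(zip(self.residue_types, self.residue_molecule))
        ]
        molecules = [Molecule(index=k, klass=c) for k, c in enumerate(self.molecule_classes)]
        bonds = [(remap[i], remap[j]) for i, j in self.bonds]
        topology = Topology(atoms, residues, molecules, bonds)
        coords = np.vstack([self.positions[old] for old in order])
        return topology, coords


def _pair_strand_runs(bb: dict[str, np.ndarray], plan: str) -> None:
    """Re-place every second E-run antiparallel to its predecessor, in place."""
    runs = []
    start = None
    for i, ch in enumerate(plan + "."):
        if ch == "E" and start is None:
            start = i
        elif ch != "E" and start is not None:
            runs.append((start, i))
            start = None
    from .stability import kabsch_superpose

    keys = ("N", "H", "CA", "C", "O", "CB")
    for a, b in zip(runs[::2], runs[1::2]):
        m = min(a[1] - a[0], b[1] - b[0])
        ia = np.arange(a[0], a[0] + m)
        ib = np.arange(b[0], b[0] + m)
        # The pairing axis (the direction the amide face points) is defined
        # on a freshly built canonical strand and carried over by rigid
        # superposition: an embedded run's own first amide H depends on the
        # preceding residue's geometry and would misorient the partner.
        ref = build_backbone("E" * m)
        rot, _, _ = kabsch_superpose(
            np.concatenate([ref[k] for k in ("N", "CA", "C", "O")]),
            np.concatenate([bb[k][ia] for k in ("N", "CA", "C", "O")]),
        )
        ca_ref = ref["CA"]
        u_ref = ca_ref[-1] - ca_ref[0]
        u_ref /= np.linalg.norm(u_ref)
        nh = ref["H"][0] - ref["N"][0]
        v_ref = nh - nh.dot(u_ref) * u_ref
        v_ref /= np.linalg.norm(v_ref)
        v = rot @ v_ref
        center = bb["CA"][ia].mean(axis=0)
        # Rodrigues 180-degree rotation about v (R x = 2 v (v.x) - x), then
        # offset along v: a rigid antiparallel copy whose residue i pairs
        # with residue m-1-i through mutual backbone H-bonds.  Pseudo
        # side-chain atoms of paired residues pack closer than a real
        # pleated sheet would allow; backbone H-bond geometry is what the
        # downstream classifiers consume.
        for key in keys:
            rel = bb[key][ia] - center
            bb[key][ib] = 2.0 * np.outer(rel @ v, v) - rel + center + _STRAND_OFFSET_NM * v


def _monomer_template(protonated: bool, flip: bool = False) -> list[tuple[str, str, np.ndarray, float]]:
    """Local atom layout of one acrylic-acid monomer: 3 carbons + carboxyl.

    Carboxyl groups alternate sides along the chain (``flip``), the
    zig-zag arrangement that keeps neighboring side groups from clashing.
    """
    atoms = [
        ("C1", "C", np.array([0.00, 0.00, 0.0]), 0.0),
        ("C2", "C", np.array([0.08, 0.12, 0.0]), 0.0),
        ("C3", "C", np.array([0.08, 0.27, 0.0]), 0.0),
        ("O1", "O", np.array([-0.02, 0.34, 0.0]), 0.0 if protonated else -0.5),
        ("O2", "O", np.array([0.18, 0.34, 0.0]), 0.0 if protonated else -0.5),
    ]
    if protonated:
        atoms.append(("HO2", "H", np.array([0.18, 0.435, 0.0]), 0.0))
    if flip:
        atoms = [(n, e, p * np.array([1.0, -1.0, 1.0]), q) for n, e, p, q in atoms]
    return atoms


def _deprotonation_pattern(n: int, fraction: float) -> np.ndarray:
    """Evenly spread deprotonation mask; fraction 0.5 charges every second monomer."""
    marks = np.floor((np.arange(n) + 1) * fraction) - np.floor(np.arange(n) * fraction)
    return marks > 0.5


def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _place_away(rng, n_points, box, occupied, min_dist=0.25):
    """Uniform points in the box at least min_dist (minimum image) from occupied."""
    out = []
    occ = np.asarray(occupied) if len(occupied) else np.empty((0, 3))
    tries = 0
    while len(out) < n_points:
        cand = rng.uniform(0.0, box, size=3)
        ok = True
        for ref in (occ, np.asarray(out) if out else np.empty((0, 3))):
            if ref.size:
                d = cand - ref
                d -= box * np.round(d / box)
                if (np.sum(d * d, axis=1) < min_dist**2).any():
                    ok = False
                    break
        if ok:
            out.append(cand)
        tries += 1
        if tries > 200 * max(n_points, 1):
            raise ValueError("box too crowded to place solvent/ions")
    return np.asarray(out)


def build_system(spec: SyntheticSpec) -> tuple[Topology, Trajectory]:
    """Construct the topology and trajectory described by ``spec``.

    Raises
    ------
    ValueError
        For inconsistent plans, a box too small for the protein (bounding
        sphere plus 2 nm), non-integral total charge, or more planted
        contacts than chains.
    """
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    plan = spec.resolved_plan()
    sequence = spec.resolved_sequence()

    # ---------------- protein ----------------
    protein_atom_pos: list[np.ndarray] = []
    residue_cb: dict[int, int] = {}
    residue_ids: list[int] = []
    if spec.n_protein_residues:
        bb = build_backbone(plan)
        _pair_strand_runs(bb, plan)
        center = bb["CA"].mean(axis=0)
        radius = max(
            float(np.linalg.norm(bb[k] - center, axis=1).max()) for k in ("N", "CA", "C", "O")
        )
        if spec.box is not None:
            box = np.asarray(spec.box, dtype=float)
            if np.any(box < 2 * radius + 2.0):
                raise ValueError(
                    f"box {tuple(box)} too small: needs >= {2 * radius + 2.0:.2f} nm per edge "
                    "(protein bounding sphere plus 2 nm)"
                )
            shift = box / 2.0 - center
        else:
            # auto-sized: build at the origin, fit the box once the chains
            # exist (their radial extent would otherwise wrap onto the protein)
            box = None
            shift = -center
        for key in bb:
            bb[key] = bb[key] + shift

        # net charge distributed +/-1 on pseudo side chains, basic/acidic first
        charge_rows: list[float] = [0.0] * spec.n_protein_residues
        q = int(spec.protein_net_charge)
        if abs(q) > spec.n_protein_residues:
            raise ValueError("cannot place more unit charges than residues")
        preferred = ["ARG", "LYS", "HIS"] if q > 0 else ["ASP", "GLU"]
        candidates = [i for i, t in enumerate(sequence) if t in preferred]
        candidates += [i for i in range(spec.n_protein_residues) if i not in candidates]
        for i in candidates[: abs(q)]:
            charge_rows[i] = float(np.sign(q))

        mol = b.new_molecule(MoleculeClass.PROTEIN)
        prev_c = None
        for i, code in enumerate(sequence):
            res = b.new_residue(code, mol)
            residue_ids.append(res)
            idx = {}
            for name in ("N", "H", "CA", "C", "O", "CB"):
                element = {"N": "N", "H": "H", "CA": "C", "C": "C", "O": "O", "CB": "C"}[name]
                charge = charge_rows[i] if name == "CB" else 0.0
                idx[name] = b.add_atom(res, name, element, bb[name][i], charge=charge)
                protein_atom_pos.append(bb[name][i])
            residue_cb[res] = idx["CB"]
            for x, y in (("N", "H"), ("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")):
                b.add_bond(idx[x], idx[y])
            if prev_c is not None:
                b.add_bond(prev_c, idx["N"])
            prev_c = idx["C"]
        protein_center = bb["CA"].mean(axis=0)
        protein_radius = radius
    else:
        box = np.asarray(spec.box, dtype=float) if spec.box is not None else None
        protein_center = (box / 2.0) if box is not None else np.zeros(3)
        protein_radius = 0.0

    # ---------------- polyelectrolyte chains ----------------
    if len(spec.planted_contacts) > spec.n_chains:
        raise ValueError(
            f"{len(spec.planted_contacts)} planted contacts but only {spec.n_chains} chains"
        )
    protein_pos_arr = np.asarray(protein_atom_pos) if protein_atom_pos else np.empty((0, 3))
    chain_dirs = _random_directions(rng, max(spec.n_chains, 1))
    used_contact_residues: set[int] = set()
    safe_r = protein_radius + 1.5

    for c in range(spec.n_chains):
        protonated_mask = ~_deprotonation_pattern(spec.monomers_per_chain, spec.deprotonated_fraction)
        planted = spec.planted_contacts[c] if c < len(spec.planted_contacts) else None
        if planted is not None:
            res_type, dist = planted
            options = [
                r
                for r in residue_ids
                if b.residue_types[r] == res_type and r not in used_contact_residues
            ]
            if not options:
                raise ValueError(f"no unused protein residue of type {res_type} for planted contact")
            target_res = options[0]
            used_contact_residues.add(target_res)
            anchor = b.positions[residue_cb[target_res]]
            out_dir = anchor - protein_center
            nrm = np.linalg.norm(out_dir)
            out_dir = out_dir / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            axis = out_dir
            # origin placed below, once the local frame exists: O1 of monomer 0
            # (the atom with the smallest projection on the outward axis) must
            # land exactly at anchor + dist * axis.
            origin = None
        else:
            # radial placement: the chain extends away from the protein
            origin = protein_center + chain_dirs[c] * (safe_r + 0.6)
            axis = chain_dirs[c]
        # local frame for the monomer template (x = chain axis)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(axis @ ref) > 0.95:
            ref = np.array([0.0, 1.0, 0.0])
        ey = np.cross(axis, ref)
        ey /= np.linalg.norm(ey)
        ez = np.cross(axis, ey)
        frame_mat = np.stack([axis, ey, ez], axis=1)
        if origin is None:
            local_o1 = np.array([-0.02, 0.34, 0.0])
            origin = anchor + dist * axis - frame_mat @ local_o1

        mol = b.new_molecule(MoleculeClass.POLYELECTROLYTE)
        prev_c1 = None
        for m in range(spec.monomers_per_chain):
            protonated = bool(protonated_mask[m])
            res = b.new_residue("AAH" if protonated else "AAD", mol)
            idx = {}
            for name, element, local, charge in _monomer_template(protonated, flip=bool(m % 2)):
                pos = origin + frame_mat @ (local + np.array([0.25 * m, 0.0, 0.0]))
                idx[name] = b.add_atom(res, name, element, pos, charge=charge)
            for x, y in (("C1", "C2"), ("C2", "C3"), ("C3", "O1"), ("C3", "O2")):
                b.add_bond(idx[x], idx[y])
            if protonated:
                b.add_bond(idx["O2"], idx["HO2"])
            if prev_c1 is not None:
                b.add_bond(prev_c1, idx["C1"])
            prev_c1 = idx["C1"]

    # ---------------- box finalization (auto-sized path) ----------------
    if box is None:
        if b.positions:
            pos = np.asarray(b.positions)
            span = pos.max(axis=0) - pos.min(axis=0)
            box = np.ceil((span + 4.0) * 10) / 10  # 2 nm clearance per side
            move = 2.0 - pos.min(axis=0)
        else:
            box = np.full(3, 5.0)
            move = np.zeros(3)
        for k in range(len(b.positions)):
            b.positions[k] = b.positions[k] + move
        protein_center = protein_center + move
        protein_atom_pos = [p + move for p in protein_atom_pos]
        protein_pos_arr = np.asarray(protein_atom_pos) if protein_atom_pos else np.empty((0, 3))

    # ---------------- planted hydrogen bonds ----------------
    class_letters = {
        "protein": MoleculeClass.PROTEIN,
        "polyelectrolyte": MoleculeClass.POLYELECTROLYTE,
        "water": MoleculeClass.WATER,
    }
    graft_count: dict[int, int] = {}
    planted_water_pos: list[np.ndarray] = []

    def protein_site(res_type: str | None, want_donor: bool) -> tuple[int, np.ndarray, int | None]:
        """Graft a hydroxyl-like (donor) or carbonyl-like (acceptor) O onto a residue."""
        options = [r for r in residue_ids if res_type is None or b.residue_types[r] == res_type]
        if not options:
            raise ValueError(f"no protein residue of type {res_type} for planted hydrogen bond")
        counts = {r: graft_count.get(r, 0) for r in options}
        res = min(options, key=lambda r: (counts[r], r))
        k = graft_count.get(res, 0)
        graft_count[res] = k + 1
        cb = b.positions[residue_cb[res]]
        # radially outward graft, fanned per repeat, so the site clears the
        # backbone and multiple grafts on one residue do not collide
        outward = cb - protein_center
        nrm = np.linalg.norm(outward)
        outward = outward / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(outward @ ref) > 0.95:
            ref = np.array([0.0, 1.0, 0.0])
        tangent = np.cross(outward, ref)
        tangent /= np.linalg.norm(tangent)
        fan = np.deg2rad(40.0 * k)
        direction = np.cos(fan) * outward + np.sin(fan) * tangent
        o_pos = cb + 0.35 * direction
        o_idx = b.add_atom(res, f"OG{k + 1}", "O", o_pos)
        h_idx = None
        if want_donor:
            h_pos = o_pos + 0.101 * direction
            h_idx = b.add_atom(res, f"HG{k + 1}", "H", h_pos)
            b.add_bond(o_idx, h_idx)
        b.add_bond(residue_cb[res], o_idx)
        return o_idx, direction, h_idx

    def paa_site(want_donor: bool) -> tuple[int, np.ndarray, int | None]:
        names = b.atom_rows
        if want_donor:
            cands = [
                k
                for k, row in enumerate(names)
                if row[1] == "HO2"
            ]
            if not cands:
                raise ValueError("planted polyelectrolyte donor needs a protonated monomer")
            h_idx = cands[len(planted_paa_used) % len(cands)]
            planted_paa_used.append(h_idx)
            # donor O2 is bonded to this H
            o_idx = next(i for i, j in b.bonds if j == h_idx)
            d = b.positions[h_idx] - b.positions[o_idx]
            return o_idx, d / np.linalg.norm(d), h_idx
        cands = [k for k, row in enumerate(names) if row[1] == "O1"]
        if not cands:
            raise ValueError("planted polyelectrolyte acceptor needs a chain")
        o_idx = cands[len(planted_paa_used) % len(cands)]
        planted_paa_used.append(o_idx)
        return o_idx, _random_directions(rng, 1)[0], None

    planted_paa_used: list[int] = []
    water_mols_planted: list[int] = []

    def water_site(want_donor: bool) -> tuple[int, np.ndarray, int | None]:
        if want_donor and spec.water_sites != 3:
            raise ValueError("planted water donor requires water_sites=3")
        pos = _place_away(rng, 1, box, protein_pos_arr, min_dist=1.0)[0]
        mol = b.new_molecule(MoleculeClass.WATER)
        res = b.new_residue("HOH", mol)
        o_idx = b.add_atom(res, "OW", "O", pos, mass=_WATER_MASS if spec.water_sites == 1 else None)
        direction = _random_directions(rng, 1)[0]
        h_idx = None
        if spec.water_sites == 3:
            h1 = b.add_atom(res, "HW1", "H", pos + 0.0957 * direction)
            ortho = _random_directions(rng, 1)[0]
            ortho -= (ortho @ direction) * direction
            ortho /= np.linalg.norm(ortho)
            ang = np.deg2rad(104.5)
            h2_dir = np.cos(ang) * direction + np.sin(ang) * ortho
            h2 = b.add_atom(res, "HW2", "H", pos + 0.0957 * h2_dir)
            b.add_bond(o_idx, h1)
            b.add_bond(o_idx, h2)
            h_idx = h1
        planted_water_pos.append(pos)
        water_mols_planted.append(mol)
        return o_idx, direction, h_idx

    def get_site(klass: str, res_type: str | None, want_donor: bool):
        if klass == "protein":
            return protein_site(res_type, want_donor)
        if klass == "polyelectrolyte":
            return paa_site(want_donor)
        if klass == "water":
            return water_site(want_donor)
        raise ValueError(f"unknown planted-bond class {klass!r}")

    for hb in spec.planted_hbonds:
        if hb.donor not in class_letters or hb.acceptor not in class_letters:
            raise ValueError(f"planted bond classes must be in {sorted(class_letters)}")
        d_idx, d_dir, h_idx = get_site(hb.donor, hb.donor_residue_type, want_donor=True)
        a_idx, _, _ = get_site(hb.acceptor, hb.acceptor_residue_type, want_donor=False)
        if h_idx is None:
            raise ValueError("donor site lacks a hydrogen")
        d_pos = b.positions[d_idx]
        h_dir = b.positions[h_idx] - d_pos
        h_dir /= np.linalg.norm(h_dir)
        b.positions[a_idx] = d_pos + 0.30 * h_dir  # on the D-H axis: HDA = 0, r_DA = 3.0 A

    # ---------------- water ----------------
    occupied = [p for p in b.positions]
    n_bulk_water = spec.n_waters - len(water_mols_planted)
    if n_bulk_water > 0:
        spots = _place_away(rng, n_bulk_water, box, occupied, min_dist=0.25)
        for pos in spots:
            mol = b.new_molecule(MoleculeClass.WATER)
            res = b.new_residue("HOH", mol)
            o_idx = b.add_atom(
                res, "OW", "O", pos, mass=_WATER_MASS if spec.water_sites == 1 else None
            )
            if spec.water_sites == 3:
                d1 = _random_directions(rng, 1)[0]
                ortho = _random_directions(rng, 1)[0]
                ortho -= (ortho @ d1) * d1
                ortho /= np.linalg.norm(ortho)
                ang = np.deg2rad(104.5)
                d2 = np.cos(ang) * d1 + np.sin(ang) * ortho
                h1 = b.add_atom(res, "HW1", "H", pos + 0.0957 * d1)
                h2 = b.add_atom(res, "HW2", "H", pos + 0.0957 * d2)
                b.add_bond(o_idx, h1)
                b.add_bond(o_idx, h2)
            occupied.append(pos)

    # ---------------- counterions ----------------
    net = b.total_charge()
    if abs(net - round(net)) > 1e-6:
        raise ValueError(f"non-integral solute charge {net}")
    # one monovalent species only, sized to the actually built solute charge
    n_cat, n_an = counterions_for_neutrality(ChargeSpec(protein_net_charge=round(net)))
    ion_positions = _place_away(rng, n_cat + n_an, box, occupied, min_dist=0.3)
    for k in range(n_cat):
        mol = b.new_molecule(MoleculeClass.CATION)
        res = b.new_residue("NA", mol)
        b.add_atom(res, "NA", "NA", ion_positions[k], charge=1.0, lj=(0.23, 0.45))
    for k in range(n_an):
        mol = b.new_molecule(MoleculeClass.ANION)
        res = b.new_residue("CL", mol)
        b.add_atom(res, "CL", "CL", ion_positions[n_cat + k], charge=-1.0, lj=(0.43, 0.45))

    topology, base = b.finish(box)

    if spec.planted_contacts and spec.n_protein_residues:
        # loud failure if periodic wrapping defeated the planted construction
        prot = base[topology.class_atom_indices(MoleculeClass.PROTEIN)]
        paa = base[topology.class_atom_indices(MoleculeClass.POLYELECTROLYTE)]
        d = prot[:, None, :] - paa[None, :, :]
        d -= box * np.round(d / box)
        dmin = float(np.sqrt((d * d).sum(axis=2)).min())
        want = min(dist for _, dist in spec.planted_contacts)
        if abs(dmin - want) > 1e-6:
            raise ValueError(
                f"planted contact construction failed: global minimum {dmin:.4f} nm != "
                f"{want:.4f} nm (box too small or chains too long?)"
            )

    frames = []
    for k in range(spec.n_frames):
        if k == 0 or spec.jitter_sigma == 0.0:
            coords = base.copy()
        else:
            coords = base + rng.normal(0.0, spec.jitter_sigma, size=base.shape)
        frames.append(Frame(coords, box.copy(), time=k * spec.frame_spacing))
    return topology, Trajectory(topology, frames)


def ideal_gas(
    n_points: int, box: Sequence[float], n_frames: int, seed: int = 0
) -> Trajectory:
    """Uniform i.i.d. points per frame: the g(r) = 1 reference system."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    atoms, residues, molecules = [], [], []
    for k in range(n_points):
        molecules.append(Molecule(index=k, klass=MoleculeClass.OTHER))
        residues.append(Residue(index=k, type_code="GAS", molecule_index=k))
        atoms.append(Atom(index=k, name="P", element="C", mass=1.0, residue_index=k))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        topology = Topology(atoms, residues, molecules)
    frames = [
        Frame(rng.uniform(0.0, box, size=(n_points, 3)), box.copy(), time=float(k))
        for k in range(n_frames)
    ]
    return Trajectory(topology, frames)
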