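"""Domain model for periodic molecular systems.

Holds the containers every analysis stage operates on: :class:`Atom`,
:class:`Residue`, :class:`Molecule`, an indexed :class:`Topology`,
per-frame coordinates in a :class:`Frame`, and an ordered
:class:`Trajectory`.  All coordinates and box lengths are stored in
nanometres; times in nanoseconds; charges in elementary charges;
Lennard-Jones parameters in nm / kJ/mol.  Only orthorhombic boxes are
supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "MoleculeClass",
    "Atom",
    "Residue",
    "Molecule",
    "Topology",
    "Frame",
    "Trajectory",
    "AnalysisWindow",
    "minimum_image_displacement",
    "minimum_image_distance",
    "classify_residue",
    "AMINO_ACIDS",
    "ELEMENT_MASSES",
]


class MoleculeClass(str, Enum):
    """Coarse chemical identity of a molecule in the system."""

    PROTEIN = "protein"
    POLYELECTROLYTE = "polyelectrolyte"
    WATER = "water"
    CATION = "cation"
    ANION = "anion"
    OTHER = "other"


#: The 20 standard amino-acid three-letter codes.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Acrylic-acid monomer codes: protonated (neutral) and deprotonated (charged).
MONOMER_CODES = frozenset({"AAH", "AAD"})
WATER_CODES = frozenset({"HOH", "SOL", "WAT", "TIP3", "SPC"})
CATION_CODES = frozenset({"NA", "SOD", "K"})
ANION_CODES = frozenset({"CL", "CLA"})

ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
}


def classify_residue(type_code: str) -> MoleculeClass:
    """Map a residue/monomer code onto a molecule class.

    Unknown codes fall back to :attr:`MoleculeClass.OTHER` with a warning, so
    that foreign structure files still load.
    """
    code = type_code.upper()
    if code in AMINO_ACIDS:
        return MoleculeClass.PROTEIN
    if code in MONOMER_CODES:
        return MoleculeClass.POLYELECTROLYTE
    if code in WATER_CODES:
        return MoleculeClass.WATER
    if code in CATION_CODES:
        return MoleculeClass.CATION
    if code in ANION_CODES:
        return MoleculeClass.ANION
    warnings.warn(f"unknown residue code {type_code!r}; assigning generic class")
    return MoleculeClass.OTHER


@dataclass(frozen=True)
class Atom:
    """A point particle with force-field metadata.

    ``lj_sigma``/``lj_epsilon`` default to zero, i.e. a non-interacting site
    as far as the van der Waals term is concerned.
    """

    index: int
    name: str
    element: str
    mass: float
    partial_charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    residue_index: int = 0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.index}: mass must be positive, got {self.mass}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.index}: LJ parameters must be non-negative")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass(frozen=True)
class Residue:
    """One amino acid, monomer, water, or ion."""

    index: int
    type_code: str
    molecule_index: int


@dataclass(frozen=True)
class Molecule:
    index: int
    klass: MoleculeClass


class Topology:
    """Immutable indexed view over atoms, residues, molecules, and bonds.

    Builds flat numpy arrays for the per-atom quantities the analysis
    stages need (masses, charges, LJ parameters, class membership) so that
    selections are cheap.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        residues: Sequence[Residue],
        molecules: Sequence[Molecule],
        bonds: Iterable[tuple[int, int]] = (),
    ) -> None:
        self.atoms = list(atoms)
        self.residues = list(residues)
        self.molecules = list(molecules)
        self.bonds = [(min(i, j), max(i, j)) for i, j in bonds]

        n = len(self.atoms)
        self.names = np.array([a.name for a in self.atoms], dtype=object)
        self.elements = np.array([a.element.upper() for a in self.atoms], dtype=object)
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.charges = np.array([a.partial_charge for a in self.atoms], dtype=float)
        self.lj_sigma = np.array([a.lj_sigma for a in self.atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms], dtype=float)
        self.residue_indices = np.array([a.residue_index for a in self.atoms], dtype=int)
        self.is_hydrogen = self.elements == "H"

        for a in self.atoms:
            if not 0 <= a.residue_index < len(self.residues):
                raise ValueError(f"atom {a.index} references missing residue {a.residue_index}")
        for r in self.residues:
            if not 0 <= r.molecule_index < len(self.molecules):
                raise ValueError(f"residue {r.index} references missing molecule {r.molecule_index}")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references missing atoms")

        res_mol = np.array([r.molecule_index for r in self.residues], dtype=int)
        self.molecule_indices = res_mol[self.residue_indices]
        mol_class = np.array([m.klass for m in self.molecules], dtype=object)
        self.atom_classes = mol_class[self.molecule_indices]
        self.residue_classes = mol_class[res_mol]
        self.residue_types = np.array([r.type_code for r in self.residues], dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def class_atom_indices(self, klass: MoleculeClass) -> np.ndarray:
        """Indices of all atoms belonging to molecules of ``klass``."""
        # compare on the value string: numpy coerces a bare str-Enum scalar badly
        return np.flatnonzero(self.atom_classes == klass.value)

    def class_residue_indices(self, klass: MoleculeClass) -> np.ndarray:
        return np.flatnonzero(self.residue_classes == klass.value)

    def calpha_indices(self) -> np.ndarray:
        """Indices of protein Cα atoms, in residue order."""
        mask = (self.names == "CA") & (self.atom_classes == MoleculeClass.PROTEIN.value)
        return np.flatnonzero(mask)

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        return np.flatnonzero(self.residue_indices == residue_index)

    def donor_hydrogens(self) -> dict[int, list[int]]:
        """Map heavy-atom donor index -> indices of its covalently bound hydrogens.

        Donors are N and O atoms with at least one bound H, derived from the
        bond list.
        """
        out: dict[int, list[int]] = {}
        for i, j in self.bonds:
            for heavy, h in ((i, j), (j, i)):
                if self.elements[h] == "H" and self.elements[heavy] in ("N", "O"):
                    out.setdefault(int(heavy), []).append(int(h))
        return out

    def bonded_exclusions(self, max_separation: int = 2) -> set[tuple[int, int]]:
        """Atom pairs separated by <= ``max_separation`` bonds (1-2 and 1-3 by default)."""
        adjacency: dict[int, set[int]] = {}
        for i, j in self.bonds:
            adjacency.setdefault(i, set()).add(j)
            adjacency.setdefault(j, set()).add(i)
        excluded: set[tuple[int, int]] = set()
        for start in adjacency:
            frontier = {start}
            seen = {start}
            for _ in range(max_separation):
                frontier = {nb for a in frontier for nb in adjacency.get(a, ())} - seen
                for other in frontier:
                    excluded.add((min(start, other), max(start, other)))
                seen |= frontier
        return excluded

    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class Frame:
    """Coordinates (nm) of all atoms at one time point, with the periodic box."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError(f"coordinates must be (n, 3), got {self.coordinates.shape}")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError(f"box must be three positive lengths, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def wrapped(self) -> np.ndarray:
        """Coordinates folded into [0, box)."""
        return np.mod(self.coordinates, self.box)


class Trajectory:
    """Time-ordered frames sharing one topology."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]) -> None:
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        for k, f in enumerate(frames):
            if f.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"frame {k} has {f.n_atoms} atoms but topology has {topology.n_atoms}"
                )
        times = [f.time for f in frames]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")
        self.topology = topology
        self.frames = list(frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, k: int) -> Frame:
        return self.frames[k]

    def coordinate_array(self) -> np.ndarray:
        """All coordinates as one (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class AnalysisWindow:
    """Fraction-of-trajectory window; the default keeps the second half
    ("steady state": the last 100 ns of a 200 ns run)."""

    start_fraction: float = 0.5
    end_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.start_fraction < self.end_fraction <= 1.0:
            raise ValueError(
                f"window fractions must satisfy 0 <= start < end <= 1, got "
                f"({self.start_fraction}, {self.end_fraction})"
            )

    def frame_indices(self, n_frames: int) -> np.ndarray:
        lo = int(np.floor(self.start_fraction * n_frames))
        hi = int(np.ceil(self.end_fraction * n_frames))
        return np.arange(lo, hi)

    def select(self, traj: Trajectory) -> list[Frame]:
        return [traj.frames[k] for k in self.frame_indices(traj.n_frames)]


def minimum_image_displacement(p1: np.ndarray, p2: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shortest displacement vector(s) p1 - p2 under orthorhombic periodicity."""
    d = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(p1: np.ndarray, p2: np.ndarray, box: np.ndarray) -> float | np.ndarray:
    """Minimum-image distance between points (or arrays of points)."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError(f"box lengths must be positive, got {box}")
    d = minimum_image_displacement(p1, p2, box)
    return np.sqrt(np.sum(d * d, axis=-1))
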