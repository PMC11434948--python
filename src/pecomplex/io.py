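"""Readers and writers for PDB, GRO, and box-annotated multi-frame XYZ.

Internal units are nm; PDB coordinates are converted from/to Å at this
boundary.  Indices are 0-based internally and serialized 1-based.  Writers
emit the standard fixed-column layouts; readers tolerate trailing
whitespace and report malformed records with their line number.

The XYZ variant used for trajectories carries the periodic box and the
frame time on the comment line as ``box=Lx,Ly,Lz time=t`` (nm / ns).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    Atom,
    Frame,
    Molecule,
    MoleculeClass,
    Residue,
    Topology,
    Trajectory,
    ELEMENT_MASSES,
    classify_residue,
)

__all__ = [
    "ParseError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "build_topology",
    "infer_bonds",
]

NM_PER_ANGSTROM = 0.1


class ParseError(ValueError):
    """Raised for malformed records; carries the offending line number."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


@dataclass
class _AtomRecord:
    name: str
    residue_code: str
    residue_serial: int
    chain_id: str
    position: np.ndarray
    element: str = ""


def _element_from_name(name: str, residue_code: str) -> str:
    code = residue_code.upper()
    if code in ("NA", "SOD", "K"):
        return "NA" if code in ("NA", "SOD") else "K"
    if code in ("CL", "CLA"):
        return "CL"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def build_topology(records: list[_AtomRecord], infer_elements: bool = True) -> Topology:
    """Assemble a :class:`Topology` from parsed atom records.

    Molecule boundaries: a new molecule starts whenever the chain identifier
    changes, the molecule class changes, or the residue belongs to a
    single-residue species (water, ions).
    """
    atoms: list[Atom] = []
    residues: list[Residue] = []
    molecules: list[Molecule] = []
    prev_key: tuple[str, int] | None = None
    prev_class: MoleculeClass | None = None
    prev_chain: str | None = None
    for k, rec in enumerate(records):
        element = rec.element or (_element_from_name(rec.name, rec.residue_code) if infer_elements else "C")
        klass = classify_residue(rec.residue_code)
        key = (rec.chain_id, rec.residue_serial)
        if key != prev_key:
            single = klass in (MoleculeClass.WATER, MoleculeClass.CATION, MoleculeClass.ANION)
            if (
                not molecules
                or single
                or klass != prev_class
                or rec.chain_id != prev_chain
            ):
                molecules.append(Molecule(index=len(molecules), klass=klass))
            residues.append(
                Residue(index=len(residues), type_code=rec.residue_code, molecule_index=len(molecules) - 1)
            )
            prev_key, prev_class, prev_chain = key, klass, rec.chain_id
        mass = ELEMENT_MASSES.get(element.upper(), 12.011)
        atoms.append(
            Atom(
                index=k,
                name=rec.name,
                element=element,
                mass=mass,
                residue_index=len(residues) - 1,
            )
        )
    return Topology(atoms, residues, molecules)


def infer_bonds(topology: Topology, frame: Frame) -> list[tuple[int, int]]:
    """Distance-based covalent bond perception within molecules.

    X–H pairs closer than 0.125 nm and heavy-heavy pairs closer than
    0.18 nm (minimum image) are bonded; pairs spanning different molecules
    never are.
    """
    pos = frame.wrapped()
    tree = cKDTree(pos, boxsize=frame.box)
    bonds: list[tuple[int, int]] = []
    for i, j in tree.query_pairs(r=0.18):
        if topology.molecule_indices[i] != topology.molecule_indices[j]:
            continue
        d = np.linalg.norm(
            (pos[i] - pos[j]) - frame.box * np.round((pos[i] - pos[j]) / frame.box)
        )
        h = topology.is_hydrogen[i] or topology.is_hydrogen[j]
        if topology.is_hydrogen[i] and topology.is_hydrogen[j]:
            continue
        if (h and d <= 0.125) or (not h and d <= 0.18):
            bonds.append((min(i, j), max(i, j)))
    return sorted(bonds)


def _detect_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "gro", "xyz"):
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


# ---------------------------------------------------------------------------
# PDB

def _read_pdb(path: str | os.PathLike) -> tuple[Topology, Frame]:
    records: list[_AtomRecord] = []
    box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "CRYST1":
                try:
                    box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    ) * NM_PER_ANGSTROM
                except ValueError as exc:
                    raise ParseError(path, lineno, f"malformed CRYST1 record: {exc}") from exc
            elif tag in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(path, lineno, "ATOM record shorter than coordinate fields")
                try:
                    name = line[12:16].strip()
                    res_code = line[17:20].strip()
                    chain = line[21].strip() or "A"
                    res_serial = int(line[22:26])
                    xyz = np.array(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    ) * NM_PER_ANGSTROM
                except ValueError as exc:
                    raise ParseError(path, lineno, f"malformed ATOM record: {exc}") from exc
                element = line[76:78].strip() if len(line) >= 78 else ""
                records.append(
                    _AtomRecord(name, res_code, res_serial, chain, xyz, element)
                )
    if not records:
        raise ParseError(path, 0, "no ATOM/HETATM records found")
    if box is None:
        span = np.vstack([r.position for r in records])
        box = np.maximum(span.max(axis=0) - span.min(axis=0) + 2.0, 1.0)
    topology = build_topology(records)
    frame = Frame(np.vstack([r.position for r in records]), box)
    return topology, frame


def _write_pdb(path: str | os.PathLike, topology: Topology, frame: Frame) -> None:
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    with open(path, "w") as fh:
        a, b, c = frame.box / NM_PER_ANGSTROM
        fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for atom in topology.atoms:
            res = topology.residues[atom.residue_index]
            mol = res.molecule_index
            chain = chain_letters[mol % len(chain_letters)]
            x, y, z = frame.coordinates[atom.index] / NM_PER_ANGSTROM
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            record = "ATOM  " if classify_residue(res.type_code) == MoleculeClass.PROTEIN else "HETATM"
            fh.write(
                f"{record}{(atom.index % 99999) + 1:5d} {name:<4s} {res.type_code:<3s} "
                f"{chain}{(res.index % 9999) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element[:2]:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# GRO

def _parse_gro_block(lines: list[str], start: int, path: str | os.PathLike):
    """Parse one GRO frame starting at ``lines[start]``; returns (records,
    coords, box, time, next_index)."""
    title = lines[start]
    time = 0.0
    if "t=" in title:
        try:
            time = float(title.split("t=")[1].split()[0])
        except (ValueError, IndexError):
            time = 0.0
    try:
        n_atoms = int(lines[start + 1].strip())
    except (ValueError, IndexError) as exc:
        raise ParseError(path, start + 2, f"expected atom count: {exc}") from exc
    records: list[_AtomRecord] = []
    coords = np.empty((n_atoms, 3))
    for k in range(n_atoms):
        lineno = start + 3 + k
        try:
            line = lines[start + 2 + k]
        except IndexError as exc:
            raise ParseError(path, lineno, "file truncated inside atom block") from exc
        try:
            res_serial = int(line[0:5])
            res_code = line[5:10].strip()
            name = line[10:15].strip()
            coords[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except ValueError as exc:
            raise ParseError(path, lineno, f"malformed GRO atom line: {exc}") from exc
        records.append(_AtomRecord(name, res_code, res_serial, "A", coords[k].copy()))
    box_lineno = start + 2 + n_atoms
    try:
        box = np.array([float(tok) for tok in lines[box_lineno].split()[:3]])
    except (ValueError, IndexError) as exc:
        raise ParseError(path, box_lineno + 1, f"malformed box line: {exc}") from exc
    return records, coords, box, time, box_lineno + 1


def _read_gro(path: str | os.PathLike) -> tuple[Topology, Frame]:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(path, max(len(lines), 1), "not a GRO file (fewer than 3 lines)")
    records, coords, box, time, _ = _parse_gro_block(lines, 0, path)
    return build_topology(records), Frame(coords, box, time)


def _write_gro_block(fh, topology: Topology, frame: Frame) -> None:
    fh.write(f"pecomplex system t= {frame.time:.6f}\n")
    fh.write(f"{topology.n_atoms:5d}\n")
    for atom in topology.atoms:
        res = topology.residues[atom.residue_index]
        x, y, z = frame.coordinates[atom.index]
        fh.write(
            f"{(res.index % 99999) + 1:5d}{res.type_code:<5s}{atom.name:>5s}"
            f"{(atom.index % 99999) + 1:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# XYZ (multi-frame, box-annotated)

def _read_xyz_frames(path: str | os.PathLike):
    lines = Path(path).read_text().splitlines()
    frames = []
    names: list[str] | None = None
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(path, pos + 1, f"expected atom count: {exc}") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        box = None
        time = 0.0
        for token in comment.split():
            if token.startswith("box="):
                try:
                    box = np.array([float(v) for v in token[4:].split(",")])
                except ValueError as exc:
                    raise ParseError(path, pos + 2, f"malformed box key: {exc}") from exc
            elif token.startswith("time="):
                try:
                    time = float(token[5:])
                except ValueError as exc:
                    raise ParseError(path, pos + 2, f"malformed time key: {exc}") from exc
        coords = np.empty((n_atoms, 3))
        frame_names = []
        for k in range(n_atoms):
            lineno = pos + 3 + k
            try:
                tokens = lines[pos + 2 + k].split()
            except IndexError as exc:
                raise ParseError(path, lineno, "file truncated inside frame") from exc
            if len(tokens) < 4:
                raise ParseError(path, lineno, f"expected 'name x y z', got {lines[pos + 2 + k]!r}")
            try:
                coords[k] = [float(tokens[1]), float(tokens[2]), float(tokens[3])]
            except ValueError as exc:
                raise ParseError(path, lineno, f"malformed coordinates: {exc}") from exc
            frame_names.append(tokens[0])
        if names is None:
            names = frame_names
        elif len(frame_names) != len(names):
            raise ParseError(
                path, pos + 1, f"frame {len(frames)} has {n_atoms} atoms, expected {len(names)}"
            )
        if box is None:
            span = coords.max(axis=0) - coords.min(axis=0)
            box = np.maximum(span + 2.0, 1.0)
        frames.append(Frame(coords, box, time))
        pos += 2 + n_atoms
    if not frames:
        raise ParseError(path, 1, "empty trajectory file")
    return names, frames


def _write_xyz(path: str | os.PathLike, topology: Topology, frames: list[Frame]) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            bx = ",".join(f"{v:.6f}" for v in frame.box)
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"box={bx} time={frame.time:.6f}\n")
            for atom in topology.atoms:
                x, y, z = frame.coordinates[atom.index]
                fh.write(f"{atom.name:<6s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def _generic_topology(names: list[str]) -> Topology:
    """One-atom-per-residue fallback topology for bare XYZ input."""
    atoms, residues, molecules = [], [], []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, name in enumerate(names):
            element = _element_from_name(name, "UNK")
            molecules.append(Molecule(index=k, klass=MoleculeClass.OTHER))
            residues.append(Residue(index=k, type_code="UNK", molecule_index=k))
            atoms.append(
                Atom(
                    index=k,
                    name=name,
                    element=element,
                    mass=ELEMENT_MASSES.get(element, 12.011),
                    residue_index=k,
                )
            )
    return Topology(atoms, residues, molecules)


# ---------------------------------------------------------------------------
# public API

def read_structure(path: str | os.PathLike, format: str | None = None) -> tuple[Topology, Frame]:
    """Read a single-frame structure (PDB or GRO) into (Topology, Frame)."""
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "gro":
        return _read_gro(path)
    raise ValueError(f"unsupported structure format {fmt!r} (expected pdb or gro)")


def write_structure(
    path: str | os.PathLike, topology: Topology, frame: Frame, format: str | None = None
) -> None:
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        _write_pdb(path, topology, frame)
    elif fmt == "gro":
        with open(path, "w") as fh:
            _write_gro_block(fh, topology, frame)
    else:
        raise ValueError(f"unsupported structure format {fmt!r} (expected pdb or gro)")


def read_trajectory(
    path: str | os.PathLike,
    format: str | None = None,
    topology: Topology | None = None,
) -> Trajectory:
    """Read a multi-frame XYZ or concatenated-GRO trajectory.

    For XYZ input without an explicit ``topology``, a generic one-bead-per-atom
    topology is synthesized from the atom names; pass the real topology (e.g.
    from the companion PDB) whenever class-aware analyses follow.
    """
    fmt = _detect_format(path, format)
    if fmt == "xyz":
        names, frames = _read_xyz_frames(path)
        if topology is None:
            topology = _generic_topology(names)
        elif topology.n_atoms != frames[0].n_atoms:
            raise ValueError(
                f"topology has {topology.n_atoms} atoms but trajectory frames have {frames[0].n_atoms}"
            )
        return Trajectory(topology, frames)
    if fmt == "gro":
        lines = Path(path).read_text().splitlines()
        if len(lines) < 3:
            raise ParseError(path, max(len(lines), 1), "empty trajectory file")
        frames = []
        first_records = None
        pos = 0
        while pos < len(lines):
            if not lines[pos].strip() and pos == len(lines) - 1:
                break
            records, coords, box, time, pos = _parse_gro_block(lines, pos, path)
            if first_records is None:
                first_records = records
            elif len(records) != len(first_records):
                raise ParseError(
                    path, pos, f"frame {len(frames)} has {len(records)} atoms, expected {len(first_records)}"
                )
            frames.append(Frame(coords, box, time))
        if topology is None:
            topology = build_topology(first_records)
        return Trajectory(topology, frames)
    raise ValueError(f"unsupported trajectory format {fmt!r} (expected xyz or gro)")


def write_trajectory(
    path: str | os.PathLike, trajectory: Trajectory, format: str | None = None
) -> None:
    fmt = _detect_format(path, format)
    if fmt == "xyz":
        _write_xyz(path, trajectory.topology, trajectory.frames)
    elif fmt == "gro":
        with open(path, "w") as fh:
            for frame in trajectory.frames:
                _write_gro_block(fh, trajectory.topology, frame)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r} (expected xyz or gro)")
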