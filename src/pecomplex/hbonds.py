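"""Geometric hydrogen-bond detection and per-class census.

A hydrogen bond is declared between a donor D (an N or O carrying at least
one covalent hydrogen) and an acceptor A (any N or O) when, under minimum
image geometry,

    r(D...A) <= 3.5 Å   and   angle(H-D-A) <= 30°

with both comparisons inclusive.  The angle is measured at the donor
(between the D->H and D->A directions).  Intra-residue pairs are excluded.

Bonds are aggregated per unordered molecule-class pair — polymer-polymer
(PP), polymer-water (PW), protein-protein (LL), protein-water (LW), and
polymer-protein (PL) — and per amino-acid type against the polymer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import (
    AnalysisWindow,
    Frame,
    MoleculeClass,
    Topology,
    Trajectory,
    minimum_image_displacement,
)

__all__ = ["HBond", "HBondCensus", "detect_hbonds", "census_by_class", "per_residue_hbonds"]

DISTANCE_CUTOFF_A = 3.5
ANGLE_CUTOFF_DEG = 30.0
_CUTOFF_NM = DISTANCE_CUTOFF_A / 10.0

_CLASS_LETTER = {
    MoleculeClass.POLYELECTROLYTE.value: "P",
    MoleculeClass.PROTEIN.value: "L",
    MoleculeClass.WATER.value: "W",
    MoleculeClass.CATION.value: "+",
    MoleculeClass.ANION.value: "-",
    MoleculeClass.OTHER.value: "?",
}
_LETTER_ORDER = {"P": 0, "L": 1, "W": 2, "+": 3, "-": 4, "?": 5}
#: The canonical pair keys reported even when zero.
CANONICAL_PAIRS = ("PP", "PW", "LL", "LW", "PL")


@dataclass(frozen=True)
class HBond:
    """One detected bond; distance in Å, angle in degrees (as the criteria)."""

    donor: int
    hydrogen: int
    acceptor: int
    distance_da: float
    angle_hda: float
    frame_index: int


@dataclass
class HBondCensus:
    """Mean ± sd bond count per class pair over a window."""

    mean: pd.Series
    sd: pd.Series
    per_frame: pd.DataFrame


def pair_label(class_a: str, class_b: str) -> str:
    """Canonical two-letter label of an unordered class pair (e.g. PL, LW)."""
    la, lb = _CLASS_LETTER[class_a], _CLASS_LETTER[class_b]
    if _LETTER_ORDER[lb] < _LETTER_ORDER[la]:
        la, lb = lb, la
    return la + lb


def detect_hbonds(frame: Frame, topology: Topology, frame_index: int = 0) -> list[HBond]:
    """Exhaustive geometric hydrogen-bond detection for one frame."""
    donors = topology.donor_hydrogens()
    is_no = (topology.elements == "N") | (topology.elements == "O")
    acceptors = np.flatnonzero(is_no)
    if not donors or acceptors.size == 0:
        return []
    pos = frame.wrapped()
    tree = cKDTree(pos[acceptors], boxsize=frame.box)
    res_of = topology.residue_indices
    out: list[HBond] = []
    for d, hydrogens in sorted(donors.items()):
        hits = tree.query_ball_point(pos[d], _CUTOFF_NM * (1 + 1e-12))
        for hit in sorted(hits):
            a = int(acceptors[hit])
            if a == d or res_of[a] == res_of[d]:
                continue
            v_da = minimum_image_displacement(pos[a], pos[d], frame.box)
            r_da = float(np.linalg.norm(v_da))
            # inclusive boundary, robust to float representation of 3.5 A
            if r_da * 10.0 > DISTANCE_CUTOFF_A + 1e-9:
                continue
            for h in hydrogens:
                v_dh = minimum_image_displacement(pos[h], pos[d], frame.box)
                cosang = float(
                    v_dh @ v_da / (np.linalg.norm(v_dh) * np.linalg.norm(v_da))
                )
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle <= ANGLE_CUTOFF_DEG + 1e-9:
                    out.append(
                        HBond(
                            donor=int(d),
                            hydrogen=int(h),
                            acceptor=a,
                            distance_da=r_da * 10.0,
                            angle_hda=angle,
                            frame_index=frame_index,
                        )
                    )
    return out


def census_by_class(
    traj: Trajectory, window: AnalysisWindow = AnalysisWindow()
) -> HBondCensus:
    """Bond counts per unordered molecule-class pair, mean ± sd over the window."""
    idx = window.frame_indices(traj.n_frames)
    if idx.size == 0:
        raise ValueError("window selects no frames")
    top = traj.topology
    rows = []
    for k in idx:
        bonds = detect_hbonds(traj.frames[k], top, frame_index=int(k))
        counts: dict[str, int] = {}
        for b in bonds:
            label = pair_label(top.atom_classes[b.donor], top.atom_classes[b.acceptor])
            counts[label] = counts.get(label, 0) + 1
        rows.append(counts)
    per_frame = pd.DataFrame(rows, index=idx).fillna(0).astype(int)
    for label in CANONICAL_PAIRS:
        if label not in per_frame.columns:
            per_frame[label] = 0
    per_frame = per_frame[sorted(per_frame.columns, key=lambda c: (c not in CANONICAL_PAIRS, c))]
    per_frame.index.name = "frame"
    return HBondCensus(
        mean=per_frame.mean(axis=0), sd=per_frame.std(axis=0, ddof=0), per_frame=per_frame
    )


def per_residue_hbonds(
    traj: Trajectory,
    window: AnalysisWindow = AnalysisWindow(),
    residue_types: list[str] | None = None,
) -> pd.Series:
    """Mean number of residue-polymer bonds per residue of each type.

    For each frame, every detected bond with one end in a protein residue of
    type t and the other end in the polyelectrolyte counts toward t; the
    frame-mean count is divided by the number of residues of the type.
    """
    top = traj.topology
    prot_res = top.class_residue_indices(MoleculeClass.PROTEIN)
    present = set(top.residue_types[prot_res])
    if residue_types is None:
        residue_types = sorted(present)
    unknown = set(residue_types) - present
    if unknown:
        raise ValueError(f"residue type(s) {sorted(unknown)} not present in protein")
    n_type = {t: int((top.residue_types[prot_res] == t).sum()) for t in residue_types}
    idx = window.frame_indices(traj.n_frames)
    if idx.size == 0:
        raise ValueError("window selects no frames")
    totals = {t: 0 for t in residue_types}
    pe = MoleculeClass.POLYELECTROLYTE.value
    prot = MoleculeClass.PROTEIN.value
    for k in idx:
        for b in detect_hbonds(traj.frames[k], top, frame_index=int(k)):
            ends = ((b.donor, b.acceptor), (b.acceptor, b.donor))
            for prot_end, other_end in ends:
                if top.atom_classes[prot_end] == prot and top.atom_classes[other_end] == pe:
                    t = str(top.residue_types[top.residue_indices[prot_end]])
                    if t in totals:
                        totals[t] += 1
                    break
    return pd.Series(
        {t: totals[t] / (idx.size * n_type[t]) for t in residue_types}, name="bonds_per_residue"
    )
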