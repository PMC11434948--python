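"""Minimum-distance association analysis between protein and polyelectrolyte.

For every frame, the globally closest (protein atom, polymer atom) pair is
located under minimum-image distances and attributed to the amino acid the
protein atom belongs to.  Frames whose minimum distance satisfies the
contact criterion (0.35 nm, the hydrogen-bond length scale) increment that
amino-acid type's association count; counts are reported raw and
normalized by the number of residues of the type and the number of frames
analysed (in percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import AnalysisWindow, Frame, MoleculeClass, Topology, Trajectory

__all__ = ["ContactEvent", "AssociationTable", "min_contact", "association_table", "top_associates"]

DEFAULT_CONTACT_CUTOFF_NM = 0.35


@dataclass(frozen=True)
class ContactEvent:
    """The global minimum-distance protein/polymer atom pair of one frame."""

    frame_index: int
    protein_atom: int
    paa_atom: int
    residue_index: int
    residue_type: str
    distance: float


@dataclass
class AssociationTable:
    """Per-residue-type association counts over a window.

    ``table`` columns: n_type, raw_count, frame_fraction (% of analysed
    frames), normalized_rate (% per residue of the type per frame).
    """

    table: pd.DataFrame
    n_frames: int
    cutoff: float

    def __getitem__(self, residue_type: str) -> pd.Series:
        return self.table.loc[residue_type]


def _class_selection(
    topology: Topology, heavy_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    prot = topology.class_atom_indices(MoleculeClass.PROTEIN)
    paa = topology.class_atom_indices(MoleculeClass.POLYELECTROLYTE)
    if heavy_only:
        prot = prot[~topology.is_hydrogen[prot]]
        paa = paa[~topology.is_hydrogen[paa]]
    if prot.size == 0:
        raise ValueError("no protein atoms in topology")
    if paa.size == 0:
        raise ValueError("no polyelectrolyte atoms in topology")
    return prot, paa


def min_contact(
    frame: Frame,
    topology: Topology,
    frame_index: int = 0,
    heavy_only: bool = False,
) -> ContactEvent:
    """Globally closest protein-polymer atom pair (minimum image).

    Exact ties are broken toward the lowest (protein_atom, paa_atom) index
    pair.  All atoms participate by default; ``heavy_only`` drops hydrogens.
    """
    prot, paa = _class_selection(topology, heavy_only)
    pos = frame.wrapped()
    tree = cKDTree(pos[paa], boxsize=frame.box)
    dists, nearest = tree.query(pos[prot], k=1)
    dmin = dists.min()
    # deterministic tie-break on exact equality
    cand_rows = np.flatnonzero(dists == dmin)
    best = None
    for row in cand_rows:
        p_atom = prot[row]
        hits = tree.query_ball_point(pos[p_atom], dmin * (1 + 1e-12) + 1e-12)
        for h in hits:
            d = dists[row] if h == nearest[row] else np.linalg.norm(
                (pos[p_atom] - pos[paa[h]]) - frame.box * np.round(
                    (pos[p_atom] - pos[paa[h]]) / frame.box
                )
            )
            if d <= dmin * (1 + 1e-12):
                key = (p_atom, paa[h])
                if best is None or key < best:
                    best = key
    p_atom, a_atom = best
    res = int(topology.residue_indices[p_atom])
    return ContactEvent(
        frame_index=frame_index,
        protein_atom=int(p_atom),
        paa_atom=int(a_atom),
        residue_index=res,
        residue_type=str(topology.residue_types[res]),
        distance=float(dmin),
    )


def association_table(
    traj: Trajectory,
    window: AnalysisWindow = AnalysisWindow(),
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    heavy_only: bool = False,
) -> AssociationTable:
    """Contact-criterion association counts per amino-acid type.

    Each analysed frame contributes at most one count: the amino-acid type
    of the frame's globally closest protein atom, provided the minimum
    distance is within ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    top = traj.topology
    prot_res = top.class_residue_indices(MoleculeClass.PROTEIN)
    types = sorted(set(top.residue_types[prot_res]))
    n_type = {t: int((top.residue_types[prot_res] == t).sum()) for t in types}
    raw = {t: 0 for t in types}
    idx = window.frame_indices(traj.n_frames)
    if idx.size == 0:
        raise ValueError("window selects no frames")
    for k in idx:
        ev = min_contact(traj.frames[k], top, frame_index=int(k), heavy_only=heavy_only)
        if ev.distance <= cutoff:
            raw[ev.residue_type] += 1
    n_frames = int(idx.size)
    table = pd.DataFrame(
        {
            "n_type": pd.Series(n_type),
            "raw_count": pd.Series(raw),
        }
    )
    table.index.name = "residue_type"
    table["frame_fraction"] = 100.0 * table["raw_count"] / n_frames
    table["normalized_rate"] = 100.0 * table["raw_count"] / (table["n_type"] * n_frames)
    return AssociationTable(table=table, n_frames=n_frames, cutoff=cutoff)


def top_associates(table: AssociationTable, threshold: float) -> list[str]:
    """Residue types with raw_count above ``threshold``, most frequent first
    (alphabetical within ties)."""
    t = table.table
    sel = t[t["raw_count"] > threshold]
    return sorted(sel.index, key=lambda name: (-sel.loc[name, "raw_count"], name))
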