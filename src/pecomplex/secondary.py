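"""Eight-state secondary-structure assignment from backbone geometry.

Implements the hydrogen-bond-pattern classification of Kabsch and Sander:
a backbone N-H...O=C hydrogen bond is declared when the electrostatic
energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

(distances in Å) falls below -0.5 kcal/mol.  n-turns (i -> i+3, 4, 5) and
bridge patterns derived from the bond matrix yield the eight states: coil,
β-sheet (E), β-bridge (B), bend (S), turn (T), α-helix (H), π-helix (I),
and 3_10-helix (G).  When overlapping patterns compete, the priority is
H > E/B > G > I > T > S > C (the classical convention; ``prefer_pi``
promotes π above α as some later implementations do).

Amide hydrogens are reconstructed geometrically when missing from the
input (bisector placement at 1.01 Å), so structures without explicit H are
handled.  Chain breaks (consecutive Cα further apart than 0.45 nm, or a
molecule boundary) terminate pattern propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnalysisWindow, Frame, MoleculeClass, Topology, Trajectory

__all__ = [
    "SS_CLASSES",
    "SS_LETTERS",
    "ks_hbond_energy",
    "assign_secondary_structure",
    "SSTimeline",
    "SSSummary",
    "ss_counts_timeline",
    "variation_table",
    "grouped_percentages",
]

#: Canonical class names, in a fixed reporting order.
SS_CLASSES = (
    "coil",
    "beta-sheet",
    "beta-bridge",
    "bend",
    "turn",
    "alpha-helix",
    "pi-helix",
    "310-helix",
)
SS_LETTERS = {
    "C": "coil",
    "E": "beta-sheet",
    "B": "beta-bridge",
    "S": "bend",
    "T": "turn",
    "H": "alpha-helix",
    "I": "pi-helix",
    "G": "310-helix",
}
_KS_PREFACTOR = 0.084 * 332.0  # kcal/mol * Å
KS_HBOND_CUTOFF = -0.5  # kcal/mol
_MIN_DIST_A = 0.5  # Å clash guard
BEND_ANGLE_DEG = 70.0
CHAIN_BREAK_NM = 0.45


def ks_hbond_energy(
    donor_n: np.ndarray, donor_h: np.ndarray, acceptor_o: np.ndarray, acceptor_c: np.ndarray
) -> float:
    """Kabsch-Sander electrostatic hydrogen-bond energy (kcal/mol).

    Positions in nm; a backbone bond is declared when the result is below
    -0.5 kcal/mol.  Raises for clashing atoms (any distance < 0.5 Å).
    """
    pts = [np.asarray(p, dtype=float) * 10.0 for p in (donor_n, donor_h, acceptor_o, acceptor_c)]
    n, h, o, c = pts
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST_A:
        raise ValueError("atoms closer than 0.5 Å; not a physical geometry")
    return _KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _backbone_arrays(frame: Frame, topology: Topology):
    """Per-protein-residue backbone coordinates (N, H, CA, C, O).

    Missing amide H is reconstructed on the bisector of (N->C_prev, N->CA);
    residues without an amide H at the chain start donate no bonds.
    Returns coordinate arrays plus a has_h mask and the residue indices.
    """
    prot_res = topology.class_residue_indices(MoleculeClass.PROTEIN)
    n_res = prot_res.size
    coords = frame.coordinates
    names = topology.names
    res_of_atom = topology.residue_indices
    out = {k: np.full((n_res, 3), np.nan) for k in ("N", "H", "CA", "C", "O")}
    for row, r in enumerate(prot_res):
        for a in np.flatnonzero(res_of_atom == r):
            nm = names[a]
            if nm in out and np.isnan(out[nm][row, 0]):
                out[nm][row] = coords[a]
    for key in ("N", "CA", "C", "O"):
        missing = np.isnan(out[key][:, 0])
        if missing.any():
            raise ValueError(
                f"protein residue(s) {prot_res[missing][:5]} lack backbone atom {key}"
            )
    has_h = ~np.isnan(out["H"][:, 0])
    # geometric reconstruction: H anti to the previous carbonyl, 1.01 Å from N
    for row in np.flatnonzero(~has_h):
        if row == 0:
            continue
        u1 = out["N"][row] - out["C"][row - 1]
        u2 = out["N"][row] - out["CA"][row]
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        nrm = np.linalg.norm(bis)
        if nrm > 1e-8:
            out["H"][row] = out["N"][row] + 0.101 * bis / nrm
            has_h[row] = True
    return out, has_h, prot_res


def _segment_ids(ca: np.ndarray, prot_res: np.ndarray, topology: Topology) -> np.ndarray:
    """Chain-segment id per residue; increments at breaks and molecule boundaries."""
    n = ca.shape[0]
    seg = np.zeros(n, dtype=int)
    res_mol = np.array([topology.residues[r].molecule_index for r in prot_res])
    for i in range(1, n):
        gap = np.linalg.norm(ca[i] - ca[i - 1])
        seg[i] = seg[i - 1] + (1 if (gap > CHAIN_BREAK_NM or res_mol[i] != res_mol[i - 1]) else 0)
    return seg


def _hbond_matrix(bb, has_h: np.ndarray) -> np.ndarray:
    """hb[i, j]: CO of residue i accepts a bond from NH of residue j."""
    n = bb["N"].shape[0]
    # distances in Å between acceptor (C, O of i) and donor (N, H of j)
    def dmat(a, b):
        d = a[:, None, :] - b[None, :, :]
        return np.sqrt((d * d).sum(axis=2)) * 10.0

    r_on = dmat(bb["O"], bb["N"])
    r_ch = dmat(bb["C"], bb["H"])
    r_oh = dmat(bb["O"], bb["H"])
    r_cn = dmat(bb["C"], bb["N"])
    with np.errstate(divide="ignore"):
        energy = _KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    hb = energy < KS_HBOND_CUTOFF
    idx = np.arange(n)
    hb[idx, idx] = False
    # a residue cannot donate to its own predecessor's carbonyl (bonded neighbors)
    hb[idx[:-1], idx[:-1] + 1] = False
    hb[:, ~has_h] = False
    # clash guard: reject unphysical overlaps
    hb &= np.minimum.reduce([r_on, r_ch, r_oh, r_cn]) >= _MIN_DIST_A
    return hb


def assign_secondary_structure(
    frame: Frame, topology: Topology, prefer_pi: bool = False
) -> np.ndarray:
    """One-letter state per protein residue (H/G/I/E/B/T/S/C)."""
    bb, has_h, prot_res = _backbone_arrays(frame, topology)
    n = prot_res.size
    if n == 0:
        return np.array([], dtype=object)
    seg = _segment_ids(bb["CA"], prot_res, topology)
    hb = _hbond_matrix(bb, has_h)

    # n-turns: CO(i) <- NH(i+n), all residues i..i+n in one segment
    turns = {}
    for m in (3, 4, 5):
        t = np.zeros(n, dtype=bool)
        for i in range(n - m):
            if seg[i] == seg[i + m] and hb[i, i + m]:
                t[i] = True
        turns[m] = t

    helix = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in (3, 4, 5):
        t = turns[m]
        for i in range(1, n - m):
            if t[i - 1] and t[i]:
                helix[m][i : i + m] = True

    # bridges: parallel / antiparallel patterns, |i-j| >= 3
    bridge = np.zeros(n, dtype=bool)
    partner_count = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                bridge[i] = bridge[j] = True
                partner_count[i, j] = partner_count[j, i] = True
    # ladders: a bridge extends to a sheet when a neighboring residue pair bridges too
    sheet = np.zeros(n, dtype=bool)
    for i in range(n):
        if not bridge[i]:
            continue
        for j in np.flatnonzero(partner_count[i]):
            neighbor = False
            for di in (-1, 1):
                ii = i + di
                if 0 <= ii < n and seg[ii] == seg[i]:
                    for dj in (-1, 0, 1):
                        jj = j + dj
                        if 0 <= jj < n and partner_count[ii, jj]:
                            neighbor = True
            if neighbor:
                sheet[i] = True

    # turn flag: interior residues of any n-turn
    turn_flag = np.zeros(n, dtype=bool)
    for m in (3, 4, 5):
        for i in np.flatnonzero(turns[m]):
            turn_flag[i + 1 : i + m] = True

    # bend: kink of the Cα trace above 70 degrees
    bend = np.zeros(n, dtype=bool)
    ca = bb["CA"]
    for i in range(2, n - 2):
        if seg[i - 2] != seg[i + 2]:
            continue
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) > BEND_ANGLE_DEG:
            bend[i] = True

    labels = np.full(n, "C", dtype=object)
    order = ["I", "G", "EB", "H"] if not prefer_pi else ["G", "H", "EB", "I"]
    # assign lowest priority first so higher priorities overwrite
    labels[bend] = "S"
    labels[turn_flag] = "T"
    for tag in order:
        if tag == "EB":
            labels[bridge] = "B"
            labels[sheet] = "E"
        elif tag == "H":
            labels[helix[4]] = "H"
        elif tag == "G":
            labels[helix[3]] = "G"
        elif tag == "I":
            labels[helix[5]] = "I"
    return labels


@dataclass
class SSTimeline:
    """Per-frame labels (frames x protein residues) and per-frame class counts."""

    labels: np.ndarray
    counts: pd.DataFrame
    times: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]


@dataclass
class SSSummary:
    """Window mean ± sd residue count per class."""

    mean: pd.Series
    sd: pd.Series
    n_residues: int
    n_frames: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def ss_counts_timeline(
    traj: Trajectory,
    window: AnalysisWindow = AnalysisWindow(),
    prefer_pi: bool = False,
) -> tuple[SSTimeline, SSSummary]:
    """Classify every frame; summarize class counts over the window."""
    all_labels = []
    for frame in traj:
        all_labels.append(assign_secondary_structure(frame, traj.topology, prefer_pi))
    labels = np.vstack(all_labels)
    letter_order = list(SS_LETTERS)
    counts = pd.DataFrame(
        {SS_LETTERS[c]: (labels == c).sum(axis=1) for c in letter_order},
        index=pd.RangeIndex(traj.n_frames, name="frame"),
    )[list(SS_CLASSES)]
    idx = window.frame_indices(traj.n_frames)
    if idx.size == 0:
        raise ValueError("window selects no frames")
    win = counts.iloc[idx]
    summary = SSSummary(
        mean=win.mean(axis=0),
        sd=win.std(axis=0, ddof=0),
        n_residues=labels.shape[1],
        n_frames=int(idx.size),
    )
    times = np.array([f.time for f in traj])
    return SSTimeline(labels=labels, counts=counts, times=times), summary


def variation_table(summary_a: SSSummary | pd.Series, summary_b: SSSummary | pd.Series) -> pd.Series:
    """Per-class relative change (V2 - V1) / V1 between two condition summaries.

    Classes with V1 = 0 yield NaN (undefined) rather than an error.
    """
    v1 = summary_a.mean if isinstance(summary_a, SSSummary) else summary_a
    v2 = summary_b.mean if isinstance(summary_b, SSSummary) else summary_b
    if set(v1.index) != set(v2.index):
        raise ValueError("summaries classify different class sets")
    v2 = v2.reindex(v1.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (v2 - v1) / v1
    return out.where(v1 != 0, np.nan)


#: Grouping used to compare against low-resolution spectroscopy: all helix
#: flavors pooled; sheet pooled with isolated bridges.
DEFAULT_GROUPS = {
    "helices": ("alpha-helix", "pi-helix", "310-helix"),
    "beta": ("beta-sheet", "beta-bridge"),
    "turn": ("turn",),
}


def grouped_percentages(
    summary: SSSummary | pd.Series,
    groups: dict[str, tuple[str, ...]] = DEFAULT_GROUPS,
    n_residues: int | None = None,
) -> pd.Series:
    """Percentage of residues per named union of classes: 100 * sum(means) / n."""
    means = summary.mean if isinstance(summary, SSSummary) else summary
    if n_residues is None:
        if not isinstance(summary, SSSummary):
            raise ValueError("n_residues required when passing a bare Series")
        n_residues = summary.n_residues
    out = {}
    for name, members in groups.items():
        unknown = set(members) - set(SS_CLASSES)
        if unknown:
            raise ValueError(f"unknown class name(s) {sorted(unknown)}")
        out[name] = 100.0 * float(means.reindex(list(members)).sum()) / n_residues
    return pd.Series(out)
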