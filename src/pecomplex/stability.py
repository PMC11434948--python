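"""Protein stability metrics: Cα RMSD after optimal superposition and
per-residue RMSF over a trajectory window.

RMSD against a reference structure (first frame by default) quantifies
global drift from the starting fold; per-residue RMSF over the equilibrated
window identifies locally mobile residues.  Both operate on Cα atoms by
default, matching common practice for globular proteins.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .model import AnalysisWindow, Frame, Topology, Trajectory

__all__ = ["kabsch_superpose", "superpose_coordinates", "rmsd_timeseries", "rmsf_per_residue"]


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD.
    The rotation is always proper (det = +1); the reflection branch of the
    underlying SVD is rejected.

    Raises
    ------
    ValueError
        For fewer than 3 points or (near-)collinear geometry, where the
        rotation is not uniquely determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3), got {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for superposition, got {n}")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    cm = (weights[:, None] * mobile).sum(axis=0) / wsum
    cr = (weights[:, None] * reference).sum(axis=0) / wsum
    mob_c = mobile - cm
    ref_c = reference - cr
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) geometry; superposition undefined")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c, weights=weights)
    matrix = rot.as_matrix()
    rmsd = float(rssd / np.sqrt(wsum))
    translation = cr - matrix @ cm
    return matrix, translation, rmsd


def superpose_coordinates(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """``mobile`` after optimal superposition onto ``reference``."""
    matrix, translation, _ = kabsch_superpose(mobile, reference, weights)
    return mobile @ matrix.T + translation


def _selection(topology: Topology, selection: np.ndarray | None) -> np.ndarray:
    if selection is None:
        selection = topology.calpha_indices()
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    return selection


def rmsd_timeseries(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    reference: Frame | np.ndarray | None = None,
    superpose: bool = True,
    mass_weighted: bool = False,
) -> np.ndarray:
    """RMSD (nm) of the selected atoms against a reference, per frame.

    The reference defaults to the first frame.  With ``superpose`` the
    minimum over rigid transforms is reported (Kabsch); otherwise the raw
    coordinate deviation.
    """
    sel = _selection(traj.topology, selection)
    if reference is None:
        ref = traj.frames[0].coordinates[sel]
    elif isinstance(reference, Frame):
        ref = reference.coordinates[sel]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape[0] == traj.topology.n_atoms:
            ref = ref[sel]
    weights = traj.topology.masses[sel] if mass_weighted else None
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj):
        mob = frame.coordinates[sel]
        if superpose:
            _, _, out[k] = kabsch_superpose(mob, ref, weights)
        else:
            w = np.ones(sel.size) if weights is None else weights
            sq = ((mob - ref) ** 2).sum(axis=1)
            out[k] = np.sqrt((w * sq).sum() / w.sum())
    return out


def rmsf_per_residue(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    window: AnalysisWindow = AnalysisWindow(),
    superpose: bool = True,
    reference: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (nm) over the window.

    Each window frame is superposed onto the window-mean structure (iterated
    once; ``reference="first"`` uses the first window frame instead), then
    rmsf_i = sqrt(<|r_i - <r_i>|^2>).

    Returns ``(residue_indices, rmsf)`` aligned with the selected atoms.
    """
    sel = _selection(traj.topology, selection)
    idx = window.frame_indices(traj.n_frames)
    if idx.size < 2:
        raise ValueError(f"window selects {idx.size} frame(s); need at least 2 for fluctuations")
    coords = np.stack([traj.frames[k].coordinates[sel] for k in idx])
    if superpose:
        ref = coords[0]
        aligned = np.stack([superpose_coordinates(c, ref) for c in coords])
        if reference == "mean":
            mean = aligned.mean(axis=0)
            aligned = np.stack([superpose_coordinates(c, mean) for c in coords])
        elif reference != "first":
            raise ValueError(f"reference must be 'mean' or 'first', got {reference!r}")
        coords = aligned
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    residues = traj.topology.residue_indices[sel]
    return residues, rmsf
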