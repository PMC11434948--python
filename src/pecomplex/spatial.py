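"""Center-of-mass radial distribution functions and Shrake-Rupley SASA.

g(r) is the shell-normalized histogram of minimum-image distances between
group centers of mass, relative to an ideal gas at the partner group's
number density; groups are typically protein residues, polymer monomers,
or water molecules.  SASA integrates, per atom, the fraction of
quasi-uniform test points on the probe-expanded sphere not buried inside
any neighbor's expanded sphere (test points from a deterministic golden
spiral, so no seed is involved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    AnalysisWindow,
    Frame,
    MoleculeClass,
    Topology,
    Trajectory,
    minimum_image_displacement,
)

__all__ = [
    "RDFResult",
    "SASAResult",
    "group_centers",
    "residue_groups",
    "molecule_groups",
    "rdf",
    "sasa",
    "sasa_timeseries",
    "BONDI_RADII_NM",
]

#: Bondi van der Waals radii (nm) for the elements this package produces.
BONDI_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "NA": 0.227,
    "K": 0.275,
    "CL": 0.175,
}

DEFAULT_PROBE_RADIUS_NM = 0.14
DEFAULT_SPHERE_POINTS = 960


@dataclass
class RDFResult:
    """g(r) on strictly increasing bin centers, with the raw pair counts."""

    bin_centers: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    bin_width: float
    r_max: float
    n_a: int
    n_b: int
    pair: tuple[str, str] = ("A", "B")


@dataclass
class SASAResult:
    """Total solvent-accessible area (nm^2) per frame, with window stats."""

    per_frame: np.ndarray
    frame_indices: np.ndarray
    mean: float
    sd: float


def residue_groups(topology: Topology, klass: MoleculeClass | None = None) -> list[np.ndarray]:
    """Atom-index groups, one per residue (optionally restricted to a class).

    Protein residues and polymer monomers are both residues here, so this
    yields the residue/monomer COM grouping directly.
    """
    residues = (
        topology.class_residue_indices(klass) if klass is not None else np.arange(topology.n_residues)
    )
    return [np.flatnonzero(topology.residue_indices == r) for r in residues]


def molecule_groups(topology: Topology, klass: MoleculeClass | None = None) -> list[np.ndarray]:
    mols = np.arange(len(topology.molecules))
    if klass is not None:
        mols = np.array(
            [m.index for m in topology.molecules if m.klass == klass], dtype=int
        )
    return [np.flatnonzero(topology.molecule_indices == m) for m in mols]


def group_centers(
    frame: Frame, topology: Topology, groups: list[np.ndarray]
) -> np.ndarray:
    """Mass-weighted centers with minimum-image unwrapping within each group.

    Each group is made whole around its first atom before averaging, so a
    group straddling the periodic boundary gets the wrapped-consistent COM
    rather than the box-interior average; centers are folded back into the
    box.
    """
    box = frame.box
    pos = frame.coordinates
    centers = np.empty((len(groups), 3))
    for g, idx in enumerate(groups):
        if len(idx) == 0:
            raise ValueError(f"group {g} is empty")
        masses = topology.masses[idx]
        if masses.sum() <= 0:
            raise ValueError(f"group {g} has zero total mass")
        anchor = pos[idx[0]]
        rel = minimum_image_displacement(pos[idx], anchor, box)
        com = anchor + (masses[:, None] * rel).sum(axis=0) / masses.sum()
        centers[g] = np.mod(com, box)
    return centers


def rdf(
    traj: Trajectory,
    groups_a: list[np.ndarray],
    groups_b: list[np.ndarray],
    bin_width: float = 0.005,
    r_max: float | None = None,
    window: AnalysisWindow = AnalysisWindow(0.0, 1.0),
) -> RDFResult:
    """Center-of-mass pair radial distribution function g(r).

    ``groups_a``/``groups_b`` are lists of atom-index arrays.  When the two
    group lists are identical, self-pairs are excluded and the partner
    density uses N-1 (unbiased ideal-gas reference).

    ``r_max`` defaults to 0.49 x the smallest box edge and may not exceed
    half the smallest edge (shell normalization validity).
    """
    idx = window.frame_indices(traj.n_frames)
    if idx.size == 0:
        raise ValueError("window selects no frames")
    box = traj.frames[idx[0]].box
    min_edge = float(min(b.min() for b in (traj.frames[k].box for k in idx)))
    if r_max is None:
        r_max = 0.49 * min_edge
    if r_max > 0.5 * min_edge + 1e-12:
        raise ValueError(
            f"r_max={r_max} exceeds half the smallest box edge ({0.5 * min_edge:.3f} nm); "
            "shell normalization would be invalid"
        )
    same = len(groups_a) == len(groups_b) and all(
        np.array_equal(a, b) for a, b in zip(groups_a, groups_b)
    )
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    n_a, n_b = len(groups_a), len(groups_b)
    volume = 0.0
    for k in idx:
        frame = traj.frames[k]
        ca = group_centers(frame, traj.topology, groups_a)
        cb = ca if same else group_centers(frame, traj.topology, groups_b)
        d = ca[:, None, :] - cb[None, :, :]
        d -= frame.box * np.round(d / frame.box)
        r = np.sqrt((d * d).sum(axis=2))
        if same:
            iu = np.triu_indices(n_a, k=1)
            r = r[iu]
            hist, _ = np.histogram(r, bins=edges)
            counts += 2 * hist  # ordered pairs
        else:
            hist, _ = np.histogram(r.ravel(), bins=edges)
            counts += hist
        volume += float(np.prod(frame.box))
    volume /= idx.size
    density_b = (n_b - (1 if same else 0)) / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = n_a * density_b * shell * idx.size
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(
        bin_centers=centers,
        g=g,
        counts=counts,
        bin_width=bin_width,
        r_max=float(r_max),
        n_a=n_a,
        n_b=n_b,
    )


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors via the golden-angle spiral (deterministic)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def sasa(
    frame: Frame,
    topology: Topology,
    group: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    radii: dict[str, float] | None = None,
) -> float:
    """Shrake-Rupley solvent-accessible surface area of ``group`` (nm^2).

    Occluders are the group's own atoms; the group is made whole across the
    periodic boundary before the quadrature, making the result invariant
    under rigid motion.

    Raises
    ------
    KeyError-style ValueError for elements without a tabulated radius.
    """
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        raise ValueError("empty group")
    table = dict(BONDI_RADII_NM)
    if radii:
        table.update(radii)
    elements = topology.elements[group]
    missing = sorted({e for e in elements if e not in table})
    if missing:
        raise ValueError(f"no van der Waals radius for element(s) {missing}")
    r_exp = np.array([table[e] for e in elements]) + probe_radius
    # unwrap the group around its first atom
    pos = frame.coordinates[group]
    pos = pos[0] + minimum_image_displacement(pos, pos[0], frame.box)
    sphere = golden_spiral_points(n_sphere_points)
    tree = cKDTree(pos)
    area = 0.0
    r_max = r_exp.max()
    for i in range(group.size):
        pts = pos[i] + r_exp[i] * sphere
        neighbors = [j for j in tree.query_ball_point(pos[i], r_exp[i] + r_max) if j != i]
        if neighbors:
            d = np.linalg.norm(pts[:, None, :] - pos[neighbors][None, :, :], axis=2)
            exposed = (d >= r_exp[neighbors][None, :]).all(axis=1)
        else:
            exposed = np.ones(n_sphere_points, dtype=bool)
        area += 4.0 * np.pi * r_exp[i] ** 2 * exposed.mean()
    return float(area)


def sasa_timeseries(
    traj: Trajectory,
    group: np.ndarray,
    window: AnalysisWindow = AnalysisWindow(),
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    radii: dict[str, float] | None = None,
) -> SASAResult:
    """Per-frame group SASA over the window with mean ± sd."""
    idx = window.frame_indices(traj.n_frames)
    if idx.size == 0:
        raise ValueError("window selects no frames")
    values = np.array(
        [
            sasa(traj.frames[k], traj.topology, group, probe_radius, n_sphere_points, radii)
            for k in idx
        ]
    )
    return SASAResult(
        per_frame=values,
        frame_indices=idx,
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
    )
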