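"""Internal-coordinate construction of idealized molecular geometry.

Provides the NeRF (natural extension reference frame) primitive and an
ideal peptide-backbone builder driven by per-residue (phi, psi) dihedrals,
with standard bond lengths and angles.  Used by the synthetic-system
generator to plant secondary-structure geometry that a hydrogen-bond-based
classifier must recover.

All lengths in nm, angles in degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nerf", "build_backbone", "CANONICAL_DIHEDRALS"]

# Standard backbone internal coordinates (Engh-Huber-like values).
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1231
BOND_N_H = 0.1010
BOND_CA_CB = 0.1530
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

#: (phi, psi) per planned secondary-structure letter. H: alpha helix;
#: G: 3_10 helix; I: pi helix; E: beta strand; C: extended coil
#: (polyproline-II-like, forms no backbone hydrogen-bond pattern).
CANONICAL_DIHEDRALS = {
    "H": (-57.0, -47.0),
    "G": (-49.0, -26.0),
    "I": (-57.0, -70.0),
    "E": (-139.0, 135.0),
    "C": (-75.0, 150.0),
}


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D given chain A-B-C, bond |CD|, angle B-C-D, dihedral A-B-C-D."""
    theta = np.deg2rad(angle)
    phi = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(phi), bond * np.sin(theta) * np.sin(phi)]
    )
    return c + m @ d_local


def build_backbone(ss_plan: str) -> dict[str, np.ndarray]:
    """Ideal backbone (N, H, CA, C, O, CB) for a chain following ``ss_plan``.

    Each residue's (phi, psi) comes from :data:`CANONICAL_DIHEDRALS`; omega
    is trans.  Amide hydrogens sit on the bisector of the two N-neighbor
    directions (the usual reconstruction when H is absent from input);
    carbonyl O is placed in the peptide plane anti to the next amide N.

    Returns arrays of shape (n_residues, 3) per atom name.
    """
    n_res = len(ss_plan)
    if n_res == 0:
        raise ValueError("empty secondary-structure plan")
    bad = set(ss_plan) - set(CANONICAL_DIHEDRALS)
    if bad:
        raise ValueError(f"unknown plan letters {sorted(bad)}; allowed: HGIEC")
    phis = np.array([CANONICAL_DIHEDRALS[s][0] for s in ss_plan])
    psis = np.array([CANONICAL_DIHEDRALS[s][1] for s in ss_plan])

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))

    # Bootstrap residue 0 in the xy-plane.
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_res):
        N[i] = nerf(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        CA[i] = nerf(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = nerf(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phis[i])

    O = np.zeros((n_res, 3))
    for i in range(n_res):
        if i + 1 < n_res:
            # anti to the next amide N across the C=O bond
            O[i] = nerf(N[i + 1], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            O[i] = nerf(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)

    H = np.zeros((n_res, 3))
    for i in range(n_res):
        if i == 0:
            # terminal amide H: in-plane, roughly anti to CA
            u = N[0] - CA[0]
            u = u / np.linalg.norm(u)
            v = np.array([u[1], -u[0], 0.0])
            H[0] = N[0] + BOND_N_H * (u * np.cos(np.deg2rad(60)) + v * np.sin(np.deg2rad(60)))
        else:
            u1 = N[i] - C[i - 1]
            u1 /= np.linalg.norm(u1)
            u2 = N[i] - CA[i]
            u2 /= np.linalg.norm(u2)
            bis = u1 + u2
            H[i] = N[i] + BOND_N_H * bis / np.linalg.norm(bis)

    CB = np.zeros((n_res, 3))
    for i in range(n_res):
        CB[i] = nerf(N[i], C[i], CA[i], BOND_CA_CB, 110.5, 122.55)

    return {"N": N, "H": H, "CA": CA, "C": C, "O": O, "CB": CB}
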