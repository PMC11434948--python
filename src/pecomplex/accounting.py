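"""Composition and charge bookkeeping for protein/polyelectrolyte solutions.

Covers the arithmetic that fixes a simulated or experimental system before
any trajectory exists: how many counterions electroneutrality demands, the
polymer/protein mass ratio at bulk charge stoichiometry, the Bjerrum length
of the solvent, and the ionic strength of an explicit ion inventory.

Conventions: each deprotonated acrylic-acid monomer carries charge −1, so a
chain with deprotonation fraction f contributes −f per monomer on average
(f = 0.5 charges every second monomer); the protein's net charge is taken
as given (+8 for hen lysozyme at pH 7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

__all__ = [
    "ChargeSpec",
    "counterions_for_neutrality",
    "charge_neutral_mass_ratio",
    "bjerrum_length",
    "ionic_strength",
    "COULOMB_CONSTANT_KJ_NM",
]

#: Coulomb prefactor e^2/(4 pi eps0), in kJ/mol * nm / e^2 (fixed for bit-stable sums).
COULOMB_CONSTANT_KJ_NM = 138.935458

#: Relative permittivity of water at 298 K used throughout the defaults.
WATER_EPSILON_R = 78.4


@dataclass(frozen=True)
class ChargeSpec:
    """Charged-species inventory of one protein plus polyelectrolyte chains."""

    protein_net_charge: float
    protein_molar_mass: float = 14000.0
    n_chains: int = 0
    monomers_per_chain: int = 40
    monomer_molar_mass: float = 70.0
    deprotonated_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.protein_molar_mass <= 0 or self.monomer_molar_mass <= 0:
            raise ValueError("molar masses must be positive")
        if not 0.0 <= self.deprotonated_fraction <= 1.0:
            raise ValueError(
                f"deprotonated_fraction must lie in [0, 1], got {self.deprotonated_fraction}"
            )
        if self.n_chains < 0 or self.monomers_per_chain < 0:
            raise ValueError("chain counts must be non-negative")


def counterions_for_neutrality(spec: ChargeSpec) -> tuple[int, int]:
    """Counterions (n_cations, n_anions) restoring exact electroneutrality.

    The solute charge is the protein net charge plus −1 per deprotonated
    monomer; only one ion species is ever added (monovalent Na+ or Cl−).

    Raises
    ------
    ValueError
        If the per-chain deprotonated monomer count (and hence the total
        solute charge) is not integral.
    """
    per_chain = spec.deprotonated_fraction * spec.monomers_per_chain
    if abs(per_chain - round(per_chain)) > 1e-9:
        raise ValueError(
            f"deprotonated monomers per chain must be integral, got {per_chain}"
        )
    solute = spec.protein_net_charge - spec.n_chains * round(per_chain)
    if abs(solute - round(solute)) > 1e-9:
        raise ValueError(f"total solute charge must be integral, got {solute}")
    solute = int(round(solute))
    if solute > 0:
        return 0, solute
    return -solute, 0


def charge_neutral_mass_ratio(spec: ChargeSpec) -> float:
    """Polymer/protein mass ratio r_m at bulk charge stoichiometry.

    r_m = (q_protein / M_protein) / (f / M_monomer): the mass of polymer per
    mass of protein needed so polymer charge exactly balances protein charge.
    +8 / 14,000 g/mol against 0.5 / 70 g/mol gives 0.08.
    """
    if spec.protein_net_charge <= 0:
        raise ValueError("protein_net_charge must be positive for a polyanion partner")
    if spec.deprotonated_fraction == 0:
        raise ValueError("monomer charge fraction is zero; ratio undefined")
    charge_per_protein_mass = spec.protein_net_charge / spec.protein_molar_mass
    charge_per_monomer_mass = spec.deprotonated_fraction / spec.monomer_molar_mass
    return charge_per_protein_mass / charge_per_monomer_mass


def bjerrum_length(temperature: float = 298.0, relative_permittivity: float = WATER_EPSILON_R) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r kB T), in nm.

    The distance at which two unit charges interact with thermal energy kB T;
    about 0.7 nm in water at 298 K.
    """
    if temperature <= 0 or relative_permittivity <= 0:
        raise ValueError("temperature and permittivity must be positive")
    lb_m = constants.e**2 / (
        4.0 * np.pi * constants.epsilon_0 * relative_permittivity * constants.k * temperature
    )
    return lb_m * 1e9


def ionic_strength(ion_counts: dict[str, tuple[int, int]], box_volume_nm3: float) -> float:
    """Ionic strength I = 1/2 sum_i c_i z_i^2 in mol/L.

    Parameters
    ----------
    ion_counts:
        Mapping species name -> (count, valence).
    box_volume_nm3:
        Volume in nm^3 (1 nm^3 = 1e-24 L).
    """
    if box_volume_nm3 <= 0:
        raise ValueError("box volume must be positive")
    litres = box_volume_nm3 * 1e-24
    total = 0.0
    for count, valence in ion_counts.values():
        conc = count / (constants.N_A * litres)
        total += conc * valence**2
    return 0.5 * total
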