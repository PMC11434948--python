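"""Shared fixtures: small synthetic systems exercised across the suite."""

import numpy as np
import pytest

from pecomplex.model import AnalysisWindow
from pecomplex.synthetic import PlantedHBond, SyntheticSpec, build_system

FULL_WINDOW = AnalysisWindow(0.0, 1.0)


@pytest.fixture(scope="session")
def helix_system():
    """12-residue chain with a planted 10-residue α-helix, light jitter."""
    spec = SyntheticSpec(
        n_protein_residues=12,
        ss_plan="CHHHHHHHHHHC",
        seed=101,
        n_frames=5,
        jitter_sigma=0.005,
    )
    return build_system(spec)


@pytest.fixture(scope="session")
def contact_system():
    """Protein with one TYR and a polymer chain planted at 0.30 nm from it."""
    spec = SyntheticSpec(
        n_protein_residues=10,
        ss_plan="C" * 10,
        sequence=tuple(["ALA"] * 4 + ["TYR"] + ["ALA"] * 5),
        n_chains=1,
        monomers_per_chain=5,
        planted_contacts=(("TYR", 0.30),),
        seed=102,
        n_frames=6,
    )
    return build_system(spec)


@pytest.fixture(scope="session")
def hbond_system():
    """Coil protein plus chain with planted PL and LL hydrogen bonds."""
    spec = SyntheticSpec(
        n_protein_residues=6,
        ss_plan="C" * 6,
        n_chains=1,
        monomers_per_chain=4,
        planted_hbonds=(
            PlantedHBond("protein", "polyelectrolyte"),
            PlantedHBond("protein", "polyelectrolyte"),
            PlantedHBond("protein", "protein"),
        ),
        seed=103,
        n_frames=3,
    )
    return build_system(spec)


@pytest.fixture(scope="session")
def mixture_system():
    """Composition mirror of the studied mixture at toy scale: charged
    protein, several chains, waters, counterions."""
    spec = SyntheticSpec(
        n_protein_residues=16,
        ss_plan="CC" + "H" * 12 + "CC",
        protein_net_charge=4,
        n_chains=2,
        monomers_per_chain=8,
        n_waters=30,
        seed=104,
        n_frames=6,
        jitter_sigma=0.01,
    )
    return build_system(spec)
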