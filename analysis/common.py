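"""Shared study definitions for the analysis scripts.

Two toy conditions stand in for the cold/hot trajectories: identical
composition (one charged protein, polyelectrolyte chains at 50%
deprotonation, counterions), with the thermal difference emulated as a
larger positional jitter at the "hot" condition.  Everything is seeded,
so every script regenerates identical systems.
"""

from pathlib import Path

from pecomplex.synthetic import SyntheticSpec, build_system

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: 30-residue protein: one helix, one antiparallel strand pair, coil linkers.
SS_PLAN = "CC" + "H" * 10 + "CC" + "E" * 6 + "CC" + "E" * 6
N_RES = len(SS_PLAN)

CONDITIONS = {
    "cold": 0.004,  # nm jitter
    "hot": 0.012,
}


def study_spec(jitter: float, seed: int = 2024) -> SyntheticSpec:
    return SyntheticSpec(
        n_protein_residues=N_RES,
        ss_plan=SS_PLAN,
        sequence=tuple(
            ["ALA", "ARG", "SER", "TYR", "ASN", "LYS"][i % 6] for i in range(N_RES)
        ),
        protein_net_charge=4,
        n_chains=2,
        monomers_per_chain=10,
        planted_contacts=(("ARG", 0.30), ("TYR", 0.34)),
        n_waters=40,
        seed=seed,
        n_frames=40,
        jitter_sigma=jitter,
    )


def build_condition(name: str):
    return build_system(study_spec(CONDITIONS[name]))


def energetics_spec(jitter: float, seed: int = 2025) -> SyntheticSpec:
    """Helix/coil-only variant for the energy decomposition: the planted
    antiparallel sheet packs its pseudo side chains unphysically close
    (idealized H-bond geometry), which would swamp the intramolecular LJ
    sums with a construction artifact."""
    return SyntheticSpec(
        n_protein_residues=24,
        ss_plan="CC" + "H" * 20 + "CC",
        sequence=tuple(["ALA", "ARG", "SER", "TYR", "ASN", "LYS"][i % 6] for i in range(24)),
        protein_net_charge=4,
        n_chains=2,
        monomers_per_chain=10,
        planted_contacts=(("ARG", 0.30),),
        n_waters=40,
        seed=seed,
        n_frames=40,
        jitter_sigma=jitter,
    )


def build_energetics_condition(name: str):
    return build_system(energetics_spec(CONDITIONS[name]))
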