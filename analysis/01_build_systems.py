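#!/usr/bin/env python
"""Build the toy study systems and write them in portable formats.

Emits, per condition, a PDB structure and a multi-frame XYZ trajectory
under results/systems/, plus a composition table.  Everything downstream
can be re-run from these files or regenerated from the seeded specs.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from common import CONDITIONS, RESULTS, build_condition
from pecomplex.io import write_structure, write_trajectory
from pecomplex.model import MoleculeClass

out = RESULTS / "systems"
out.mkdir(parents=True, exist_ok=True)

rows = {}
for name in CONDITIONS:
    top, traj = build_condition(name)
    write_structure(out / f"{name}.pdb", top, traj.frames[0])
    # a 3-frame excerpt keeps the bundle small; the full trajectory is
    # regenerated exactly from the seeded spec in common.py
    from pecomplex.model import Trajectory

    write_trajectory(out / f"{name}_excerpt.xyz", Trajectory(top, traj.frames[:3]))
    rows[name] = {
        "atoms": top.n_atoms,
        "residues": top.n_residues,
        "protein_atoms": top.class_atom_indices(MoleculeClass.PROTEIN).size,
        "paa_atoms": top.class_atom_indices(MoleculeClass.POLYELECTROLYTE).size,
        "waters": top.class_atom_indices(MoleculeClass.WATER).size,
        "cations": top.class_atom_indices(MoleculeClass.CATION).size,
        "anions": top.class_atom_indices(MoleculeClass.ANION).size,
        "frames": traj.n_frames,
        "net_charge": top.total_charge(),
    }

table = pd.DataFrame(rows).T
table.index.name = "condition"
table.to_csv(RESULTS / "systems.tsv", sep="\t")
print("system composition (both conditions share it):")
print(table.to_string())
print(f"\nwrote structures and trajectories under {out}")
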