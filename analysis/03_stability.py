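#!/usr/bin/env python
"""Protein stability under the two conditions: Cα RMSD and per-residue RMSF.

RMSD stays flat (the toy dynamics are stationary jitter around one fold)
and RMSF scales with the planted jitter, larger at the hot condition —
the same two readouts used to judge thermostability on real trajectories.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from common import CONDITIONS, RESULTS, build_condition
from pecomplex.model import AnalysisWindow
from pecomplex.stability import rmsd_timeseries, rmsf_per_residue

window = AnalysisWindow(0.5, 1.0)
rmsd_cols = {}
rmsf_cols = {}
for name in CONDITIONS:
    top, traj = build_condition(name)
    rmsd_cols[name] = rmsd_timeseries(traj)
    residues, values = rmsf_per_residue(traj, window=window)
    rmsf_cols[name] = pd.Series(values, index=residues)

rmsd_df = pd.DataFrame(rmsd_cols)
rmsd_df.index.name = "frame"
rmsd_df.to_csv(RESULTS / "rmsd.tsv", sep="\t", float_format="%.6f")
rmsf_df = pd.DataFrame(rmsf_cols)
rmsf_df.index.name = "residue"
rmsf_df.to_csv(RESULTS / "rmsf.tsv", sep="\t", float_format="%.6f")

print("mean Cα RMSD over the steady-state window (nm):")
print(rmsd_df.iloc[len(rmsd_df) // 2 :].mean().round(4).to_string())
print("\nmean per-residue RMSF (nm):")
print(rmsf_df.mean().round(4).to_string())
print("\nhot/cold RMSF ratio:", round(rmsf_df["hot"].mean() / rmsf_df["cold"].mean(), 2),
      "(jitter ratio 3.0)")
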