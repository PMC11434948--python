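"""End-to-end pipeline: run every analysis stage from one config and write
a reproducible bundle of TSV tables plus a JSON manifest.

The config (YAML) either names a synthetic-system recipe (``synthetic:``)
or input files (``structure:`` / ``trajectory:``).  Outputs are plain TSV;
the manifest records the package version, the config hash, and a checksum
per emitted file, so identical config + seed reproduce byte-identical
bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml

from . import association as assoc_mod
from . import energetics as energy_mod
from . import hbonds as hbond_mod
from . import spatial as spatial_mod
from .model import AnalysisWindow, MoleculeClass, Topology, Trajectory
from .io import read_structure, read_trajectory
from .secondary import SSSummary, ss_counts_timeline, variation_table, SS_CLASSES
from .stability import rmsd_timeseries, rmsf_per_residue
from .synthetic import SyntheticSpec, build_system

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "table2_report", "ALL_STAGES"]

ALL_STAGES = ("rmsd", "rmsf", "dssp", "contacts", "hbonds", "rdf", "sasa", "energy")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Fully serializable run description (reproducibility contract)."""

    output_dir: str
    synthetic: SyntheticSpec | None = None
    structure: str | None = None
    trajectory: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    window: tuple[float, float] = (0.5, 1.0)
    contact_cutoff_nm: float = 0.35
    hbond_distance_angstrom: float = 3.5
    hbond_angle_deg: float = 30.0
    coulomb_cutoff_nm: float = 1.0
    lj_cutoff_nm: float = 1.0
    rdf_bin_width_nm: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "contact_cutoff_nm",
            "hbond_distance_angstrom",
            "hbond_angle_deg",
            "coulomb_cutoff_nm",
            "lj_cutoff_nm",
            "rdf_bin_width_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        AnalysisWindow(*self.window)  # validates
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {ALL_STAGES}")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data.get("synthetic"):
            syn = data["synthetic"]
            if syn.get("planted_hbonds"):
                from .synthetic import PlantedHBond

                syn["planted_hbonds"] = tuple(PlantedHBond(**h) for h in syn["planted_hbonds"])
            for key in ("sequence", "box"):
                if syn.get(key) is not None:
                    syn[key] = tuple(syn[key])
            if syn.get("planted_contacts"):
                syn["planted_contacts"] = tuple((t, float(v)) for t, v in syn["planted_contacts"])
            data["synthetic"] = SyntheticSpec(**syn)
        for key in ("stages", "window"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _load_system(config: RunConfig) -> tuple[Topology, Trajectory]:
    if config.synthetic is not None:
        return build_system(config.synthetic)
    if config.structure is None and config.trajectory is None:
        raise PipelineError("config provides neither a synthetic recipe nor input paths")
    topology = None
    if config.structure is not None:
        if not Path(config.structure).exists():
            raise PipelineError(f"structure file not found: {config.structure}")
        topology, frame = read_structure(config.structure)
    if config.trajectory is not None:
        if not Path(config.trajectory).exists():
            raise PipelineError(f"trajectory file not found: {config.trajectory}")
        traj = read_trajectory(config.trajectory, topology=topology)
        return traj.topology, traj
    return topology, Trajectory(topology, [frame])


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = AnalysisWindow(*config.window)
    topology, traj = _load_system(config)

    files: list[str] = []
    failures: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        _write_tsv(df, path)
        files.append(name)

    has_protein = topology.class_atom_indices(MoleculeClass.PROTEIN).size > 0
    has_paa = topology.class_atom_indices(MoleculeClass.POLYELECTROLYTE).size > 0

    for stage in config.stages:
        try:
            if stage == "rmsd":
                values = rmsd_timeseries(traj)
                emit(
                    "rmsd.tsv",
                    pd.DataFrame(
                        {"time_ns": [f.time for f in traj], "rmsd_nm": values}
                    ).set_index(pd.RangeIndex(traj.n_frames, name="frame")),
                )
            elif stage == "rmsf":
                residues, values = rmsf_per_residue(traj, window=window)
                emit(
                    "rmsf.tsv",
                    pd.DataFrame({"residue": residues, "rmsf_nm": values}).set_index("residue"),
                )
            elif stage == "dssp":
                timeline, summary = ss_counts_timeline(traj, window=window)
                emit("dssp_counts.tsv", timeline.counts)
                emit("dssp_summary.tsv", summary.as_frame())
                labels = pd.DataFrame(
                    timeline.labels, index=pd.RangeIndex(traj.n_frames, name="frame")
                )
                emit("dssp_labels.tsv", labels)
            elif stage == "contacts":
                if not (has_protein and has_paa):
                    raise PipelineError("contacts stage needs both protein and polyelectrolyte")
                table = assoc_mod.association_table(
                    traj, window=window, cutoff=config.contact_cutoff_nm
                )
                emit("contacts.tsv", table.table)
            elif stage == "hbonds":
                census = hbond_mod.census_by_class(traj, window=window)
                emit("hbonds_census.tsv", pd.DataFrame({"mean": census.mean, "sd": census.sd}))
                if has_protein and has_paa:
                    per_res = hbond_mod.per_residue_hbonds(traj, window=window)
                    emit("hbonds_per_residue.tsv", per_res.to_frame())
            elif stage == "rdf":
                groups = {}
                if has_protein:
                    groups["protein_residues"] = spatial_mod.residue_groups(
                        topology, MoleculeClass.PROTEIN
                    )
                if has_paa:
                    groups["paa_monomers"] = spatial_mod.residue_groups(
                        topology, MoleculeClass.POLYELECTROLYTE
                    )
                names = list(groups)
                cols = {}
                centers = None
                for i, na in enumerate(names):
                    for nb in names[i:]:
                        result = spatial_mod.rdf(
                            traj,
                            groups[na],
                            groups[nb],
                            bin_width=config.rdf_bin_width_nm,
                            window=window,
                        )
                        centers = result.bin_centers
                        cols[f"{na}-{nb}"] = result.g
                if centers is not None:
                    emit("rdf.tsv", pd.DataFrame(cols, index=pd.Index(centers, name="r_nm")))
            elif stage == "sasa":
                rows = {}
                for label, klass in (
                    ("protein", MoleculeClass.PROTEIN),
                    ("paa", MoleculeClass.POLYELECTROLYTE),
                ):
                    group = topology.class_atom_indices(klass)
                    if group.size:
                        res = spatial_mod.sasa_timeseries(traj, group, window=window)
                        rows[label] = {"mean_nm2": res.mean, "sd_nm2": res.sd}
                if rows:
                    emit("sasa.tsv", pd.DataFrame(rows).T)
            elif stage == "energy":
                pairs = []
                if has_protein:
                    pairs.append(("LL", MoleculeClass.PROTEIN, MoleculeClass.PROTEIN))
                if has_paa:
                    pairs.append(("PP", MoleculeClass.POLYELECTROLYTE, MoleculeClass.POLYELECTROLYTE))
                if has_protein and has_paa:
                    pairs.append(("PL", MoleculeClass.PROTEIN, MoleculeClass.POLYELECTROLYTE))
                rows = {}
                for label, a, bclass in pairs:
                    dec = energy_mod.class_pair_energy(
                        traj,
                        a,
                        bclass,
                        window=window,
                        coulomb_cutoff=config.coulomb_cutoff_nm,
                        lj_cutoff=config.lj_cutoff_nm,
                    )
                    rows[label] = {
                        "coulomb_mean": dec.mean["coulomb"],
                        "coulomb_sd": dec.sd["coulomb"],
                        "lj_mean": dec.mean["lj"],
                        "lj_sd": dec.sd["lj"],
                    }
                if rows:
                    emit("energy.tsv", pd.DataFrame(rows).T)
        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            failures[stage] = str(exc)

    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "pecomplex",
        "version": _pkg_version("pecomplex"),
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "files": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest() for name in files
        },
        "failed_stages": failures,
        "complete": not failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "config.yaml").write_text(config_yaml)
    if failures:
        raise PipelineError(f"stage failure(s): {failures} (partial outputs flagged in manifest)")
    return manifest


def table2_report(
    summaries: dict[str, SSSummary],
    variation_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Secondary-structure comparison across conditions with variation rows.

    One ``mean``/``sd`` row pair per condition, then a
    ``variation (V1 -> V2)`` row of per-class relative changes
    (V2 - V1)/V1 for every requested condition pair.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two condition summaries")
    classes = None
    for name, s in summaries.items():
        cset = tuple(s.mean.index)
        if classes is None:
            classes = cset
        elif set(cset) != set(classes):
            raise ValueError(f"condition {name!r} classifies a different class set")
    rows = {}
    for name, s in summaries.items():
        rows[f"{name} mean"] = s.mean
        rows[f"{name} sd"] = s.sd
    if variation_pairs is None:
        names = list(summaries)
        variation_pairs = [(names[0], n) for n in names[1:]]
    for a, b in variation_pairs:
        if a not in summaries or b not in summaries:
            raise ValueError(f"variation pair ({a}, {b}) names unknown condition")
        rows[f"variation ({a} -> {b})"] = variation_table(summaries[a], summaries[b])
    return pd.DataFrame(rows).T[list(SS_CLASSES)]
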