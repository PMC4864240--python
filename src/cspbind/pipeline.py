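"""End-to-end pipeline: compose the analysis stages from a run config.

A run executes any subset of three stages:

* ``binding``    — fit saturation titrations (per-protein probe constants),
  fit competition curves, convert IC50 to Ki, write the affinity table;
* ``consensus``  — aggregate docking pose tables into consensus affinities;
* ``expression`` — comparative-Ct fold changes and a replicate summary.

Configuration comes from a YAML mapping (see :class:`RunConfig`); every
output directory also receives ``run_log.json`` recording the parameters
and seed so a run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__ as _pkg_version
from . import binding, docking, expression, io

__all__ = ["ConfigError", "RunConfig", "run_pipeline"]

VALID_STAGES = ("binding", "consensus", "expression")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Parameters for one pipeline run.

    File paths are optional per stage; a stage listed in ``stages`` must
    have the inputs it needs.  ``k_probe`` maps protein ids to probe
    dissociation constants (μM) and is only needed when no saturation
    data is supplied for those proteins.
    """

    stages: List[str]
    output_dir: str
    saturation_path: Optional[str] = None
    competition_path: Optional[str] = None
    poses_path: Optional[str] = None
    ct_path: Optional[str] = None
    k_probe: Dict[str, float] = field(default_factory=dict)
    probe_conc: float = 2.0
    undetermined_threshold: float = 100.0
    saturation_method: str = "nonlinear"
    rmsd_cutoff: float = docking.DEFAULT_RMSD_CUTOFF
    temperature: float = docking.DEFAULT_TEMPERATURE
    pose_protein_id: str = ""
    pose_ligand_id: str = ""
    n_models: Optional[int] = None
    target_gene: str = ""
    reference_gene: str = ""
    calibrator_sample: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ConfigError("no stages requested")
        unknown = [s for s in self.stages if s not in VALID_STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s) {unknown}; "
                              f"valid: {list(VALID_STAGES)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
        return cls(**data)


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise ConfigError(f"stage requires {what}, none configured")
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"{what} not found: {p}")
    return p


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the configured stages and write their outputs.

    Returns the result bundle: a dict with one entry per executed stage
    plus the run log, all also serialized under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: Dict = {}

    if "binding" in config.stages:
        k_probe = dict(config.k_probe)
        sat_fits = {}
        if config.saturation_path is not None:
            for series in io.read_saturation(
                    _require(config.saturation_path, "saturation table")):
                fit = binding.fit_saturation(series, config.saturation_method)
                sat_fits[series.protein_id] = {
                    "k_probe_uM": fit.k_probe, "b_max": fit.b_max,
                    "method": fit.method, "r2": fit.goodness}
                k_probe[series.protein_id] = fit.k_probe
        results = []
        for series in io.read_competition(
                _require(config.competition_path, "competition table"),
                probe_conc=config.probe_conc):
            if series.protein_id not in k_probe:
                raise ConfigError(
                    f"no probe constant for protein {series.protein_id!r}: "
                    "supply saturation data or a k_probe entry")
            fit = binding.fit_competition(
                series, undetermined_threshold=config.undetermined_threshold)
            results.append(binding.affinity_from_fit(
                series, fit, k_probe[series.protein_id]))
        table = binding.build_affinity_table(results)
        io.write_affinity_table(table, outdir / "affinity_table.csv")
        io.write_json(io.affinity_records(results),
                      outdir / "affinity_results.json")
        bundle["binding"] = {"saturation_fits": sat_fits,
                             "results": io.affinity_records(results)}

    if "consensus" in config.stages:
        ensemble = io.read_poses(
            _require(config.poses_path, "pose table"),
            protein_id=config.pose_protein_id,
            ligand_id=config.pose_ligand_id,
            n_models=config.n_models)
        result = docking.consensus_pipeline(
            ensemble, rmsd_cutoff=config.rmsd_cutoff,
            temperature=config.temperature)
        report = io.consensus_report(result)
        io.write_json(report, outdir / "consensus_report.json")
        bundle["consensus"] = report

    if "expression" in config.stages:
        records = io.read_ct(_require(config.ct_path, "Ct table"))
        if not (config.target_gene and config.reference_gene
                and config.calibrator_sample):
            raise ConfigError("expression stage needs target_gene, "
                              "reference_gene and calibrator_sample")
        results = expression.ddct_fold_change(
            records, config.target_gene, config.reference_gene,
            config.calibrator_sample)
        summary = expression.summarize_replicates(results)
        summary.to_csv(outdir / "expression_summary.csv", index=False)
        io.write_json([dataclasses.asdict(r) for r in results],
                      outdir / "expression_results.json")
        bundle["expression"] = [dataclasses.asdict(r) for r in results]

    log = {"version": _pkg_version, "seed": config.seed,
           "parameters": dataclasses.asdict(config)}
    io.write_json(log, outdir / "run_log.json")
    bundle["log"] = log
    return bundle
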