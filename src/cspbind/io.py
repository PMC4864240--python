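"""Delimited-text readers and writers for the analysis stages.

Canonical dialect: comma-delimited, header row, decimal point, UTF-8.
Schemas (column name -> type):

* saturation:  ``protein_id,probe_conc_uM,intensity``
* competition: ``protein_id,ligand_id,competitor_conc_uM,percent_fluorescence``
  (or ``intensity`` in place of the percent column, plus a zero-competitor
  row per series; normalized on read)
* poses (long): ``model_id,pose_index,energy_kcal_mol,atom_index,x,y,z``
  (one row per atom per pose)
* Ct table:    ``sample_id,gene_id,replicate,ct``

Malformed rows are rejected with row-numbered messages (row 1 = header).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Type, Union

import numpy as np
import pandas as pd

from .binding import AffinityResult, CompetitionSeries, SaturationSeries, normalize_fluorescence
from .docking import ConsensusAffinity, Pose, PoseEnsemble
from .expression import CtRecord

__all__ = [
    "SchemaError",
    "SATURATION_SCHEMA",
    "COMPETITION_SCHEMA",
    "POSE_SCHEMA",
    "CT_SCHEMA",
    "read_table",
    "read_saturation",
    "read_competition",
    "read_poses",
    "read_ct",
    "write_saturation",
    "write_competition",
    "write_poses",
    "write_ct",
    "write_affinity_table",
    "consensus_report",
    "affinity_records",
    "write_json",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """An input file does not conform to its declared schema."""


SATURATION_SCHEMA: Dict[str, type] = {
    "protein_id": str, "probe_conc_uM": float, "intensity": float}
COMPETITION_SCHEMA: Dict[str, type] = {
    "protein_id": str, "ligand_id": str,
    "competitor_conc_uM": float, "percent_fluorescence": float}
COMPETITION_RAW_SCHEMA: Dict[str, type] = {
    "protein_id": str, "ligand_id": str,
    "competitor_conc_uM": float, "intensity": float}
POSE_SCHEMA: Dict[str, type] = {
    "model_id": int, "pose_index": int, "energy_kcal_mol": float,
    "atom_index": int, "x": float, "y": float, "z": float}
CT_SCHEMA: Dict[str, type] = {
    "sample_id": str, "gene_id": str, "replicate": int, "ct": float}


def read_table(path: PathLike, schema: Mapping[str, type],
               delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited file and coerce columns to the schema's types.

    Raises :class:`SchemaError` on an empty file, a missing column, or a
    non-numeric value in a numeric column (citing the 1-based file row).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, sep=delimiter,
                         skipinitialspace=True, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")

    out = pd.DataFrame(index=df.index)
    for column, typ in schema.items():
        raw = df[column]
        if typ is str:
            bad = raw.isna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
                raise SchemaError(f"{path}: column {column!r}, row {row}: "
                                  "missing value")
            out[column] = raw.str.strip()
            continue
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2
            value = raw.iloc[int(bad.idxmax())]
            raise SchemaError(f"{path}: column {column!r}, row {row}: "
                              f"non-numeric value {value!r}")
        if typ is int:
            not_integral = pd.Series(~np.isclose(converted, converted.round()),
                                     index=converted.index)
            if not_integral.any():
                row = int(not_integral.idxmax()) + 2
                raise SchemaError(f"{path}: column {column!r}, row {row}: "
                                  "expected an integer")
            out[column] = converted.astype(int)
        else:
            out[column] = converted.astype(float)
    return out


# ---------------------------------------------------------------------------
# Typed readers
# ---------------------------------------------------------------------------

def read_saturation(path: PathLike, protein_conc: float = 2.0,
                    delimiter: str = ",") -> List[SaturationSeries]:
    """One :class:`SaturationSeries` per protein_id, points sorted by conc."""
    df = read_table(path, SATURATION_SCHEMA, delimiter)
    series = []
    for protein_id, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("probe_conc_uM")
        series.append(SaturationSeries(
            protein_id=str(protein_id),
            probe_conc=grp["probe_conc_uM"].to_numpy(),
            intensity=grp["intensity"].to_numpy(),
            protein_conc=protein_conc))
    return series


def read_competition(path: PathLike, probe_conc: float = 2.0,
                     delimiter: str = ",") -> List[CompetitionSeries]:
    """One :class:`CompetitionSeries` per (protein, ligand) pair.

    Accepts either the percent schema or the raw-intensity schema; raw
    intensities are normalized to the zero-competitor row of each series.
    """
    header = pd.read_csv(path, nrows=0, sep=delimiter).columns
    raw_mode = "percent_fluorescence" not in header and "intensity" in header
    schema = COMPETITION_RAW_SCHEMA if raw_mode else COMPETITION_SCHEMA
    df = read_table(path, schema, delimiter)

    series = []
    for (protein_id, ligand_id), grp in df.groupby(
            ["protein_id", "ligand_id"], sort=False):
        grp = grp.sort_values("competitor_conc_uM")
        conc = grp["competitor_conc_uM"].to_numpy()
        if raw_mode:
            zero = grp[grp["competitor_conc_uM"] == 0.0]
            if zero.empty:
                raise SchemaError(
                    f"{path}: series ({protein_id}, {ligand_id}) has raw "
                    "intensities but no zero-competitor reference row")
            pct = normalize_fluorescence(grp["intensity"].to_numpy(),
                                         float(zero["intensity"].iloc[0]))
        else:
            pct = grp["percent_fluorescence"].to_numpy()
        series.append(CompetitionSeries(
            protein_id=str(protein_id), ligand_id=str(ligand_id),
            competitor_conc=conc, percent_fluorescence=pct,
            probe_conc=probe_conc))
    return series


def read_poses(path: PathLike, protein_id: str = "", ligand_id: str = "",
               n_models: Optional[int] = None,
               delimiter: str = ",") -> PoseEnsemble:
    """Assemble a :class:`PoseEnsemble` from a long-format pose table."""
    df = read_table(path, POSE_SCHEMA, delimiter)
    poses = []
    for (model_id, pose_index), grp in df.groupby(
            ["model_id", "pose_index"], sort=True):
        grp = grp.sort_values("atom_index")
        poses.append(Pose(model_id=int(model_id), pose_index=int(pose_index),
                          energy=float(grp["energy_kcal_mol"].iloc[0]),
                          coords=grp[["x", "y", "z"]].to_numpy()))
    if n_models is None:
        n_models = int(df["model_id"].max())
    return PoseEnsemble(protein_id=protein_id, ligand_id=ligand_id,
                        n_models=n_models, poses=poses)


def read_ct(path: PathLike, delimiter: str = ",") -> List[CtRecord]:
    df = read_table(path, CT_SCHEMA, delimiter)
    return [CtRecord(sample_id=row.sample_id, gene_id=row.gene_id,
                     replicate=int(row.replicate), ct=float(row.ct))
            for row in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_saturation(series: SaturationSeries, path: PathLike) -> None:
    pd.DataFrame({
        "protein_id": series.protein_id,
        "probe_conc_uM": series.probe_conc,
        "intensity": series.intensity,
    }).to_csv(path, index=False)


def write_competition(series: CompetitionSeries, path: PathLike) -> None:
    pd.DataFrame({
        "protein_id": series.protein_id,
        "ligand_id": series.ligand_id,
        "competitor_conc_uM": series.competitor_conc,
        "percent_fluorescence": series.percent_fluorescence,
    }).to_csv(path, index=False)


def write_poses(ensemble: PoseEnsemble, path: PathLike) -> None:
    rows = []
    for pose in ensemble.poses:
        for atom_index, (x, y, z) in enumerate(pose.coords):
            rows.append((pose.model_id, pose.pose_index, pose.energy,
                         atom_index, x, y, z))
    pd.DataFrame(rows, columns=list(POSE_SCHEMA)).to_csv(path, index=False)


def write_ct(records: Sequence[CtRecord], path: PathLike) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def write_affinity_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path)


def consensus_report(result: ConsensusAffinity) -> Dict:
    """Machine-readable consensus summary (μM scale for both Kd values)."""
    return {
        "protein_id": result.protein_id,
        "ligand_id": result.ligand_id,
        "mean_energy_kcal_mol": result.mean_energy,
        "sd_energy_kcal_mol": result.sd_energy,
        "kd_uM": result.kd_uM,
        "bound": result.bound,
        "free": result.free,
        "weighted_kd_uM": result.weighted_kd_uM,
        "degenerate": result.degenerate,
        "cluster_sizes": list(result.cluster_sizes),
    }


def affinity_records(results: Sequence[AffinityResult]) -> List[Dict]:
    """Machine-readable affinity results, one record per protein-ligand pair."""
    return [asdict(r) for r in results]


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
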