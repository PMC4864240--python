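"""Seeded generators emulating the study's raw measurements.

No raw fluorescence, docking or qPCR data were deposited with the study
these analyses mirror, so each stage ships a generator producing inputs
with the statistical structure the stage assumes:

* saturation titrations on the one-site curve over 2-30 μM probe with
  multiplicative (instrument-relative) noise;
* competition curves from the competitive-displacement model, log-spaced
  over the 2-50 μM competitor range used at the bench;
* docking pose ensembles with a planted consensus cluster of given model
  occupancy and energy distribution, decoys placed >= 3x the clustering
  cutoff away;
* Ct tables with prescribed fold changes and additive cycle noise.

Every generator is a bit-exact function of its config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .binding import (CompetitionSeries, SaturationSeries,
                      competition_percent, saturation_intensity)
from .docking import DEFAULT_RMSD_CUTOFF, Pose, PoseEnsemble
from .expression import CtRecord

__all__ = [
    "SaturationConfig",
    "CompetitionConfig",
    "EnsembleConfig",
    "CtConfig",
    "simulate_saturation",
    "simulate_competition",
    "simulate_pose_ensemble",
    "simulate_ct_table",
]


@dataclass(frozen=True)
class SaturationConfig:
    """Probe-titration generator settings (defaults match the assay protocol)."""

    k_probe: float = 11.66        # μM, CSP1 probe constant
    b_max: float = 100.0          # AU
    n_points: int = 15
    conc_min: float = 2.0         # μM
    conc_max: float = 30.0        # μM
    noise_sd: float = 0.0         # relative (multiplicative) noise
    spacing: str = "linear"       # "linear" | "log"
    protein_id: str = "CSP1"
    protein_conc: float = 2.0     # μM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_probe <= 0:
            raise ValueError("k_probe must be positive")
        if self.n_points < 4:
            raise ValueError("need at least 4 points")
        if not (0 <= self.noise_sd < 1):
            raise ValueError("noise_sd must be a fraction in [0, 1)")


@dataclass(frozen=True)
class CompetitionConfig:
    """Displacement-curve generator settings (2-50 μM competitor range)."""

    ki: float = 5.719             # μM
    k_probe: float = 11.66        # μM
    probe_conc: float = 2.0       # μM
    n_points: int = 8
    conc_min: float = 2.0         # μM; widen to bracket large IC50s
    conc_max: float = 50.0        # μM
    noise_sd: float = 0.0
    protein_id: str = "CSP1"
    ligand_id: str = "linoleic_acid"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ki, self.k_probe, self.probe_conc) <= 0:
            raise ValueError("ki, k_probe and probe_conc must be positive")
        if self.n_points < 4:
            raise ValueError("need at least 4 points")


@dataclass(frozen=True)
class EnsembleConfig:
    """Pose-ensemble generator: planted consensus cluster plus decoys."""

    n_models: int = 100
    planted_occupancy: float = 0.6    # fraction of models with the consensus pose
    energy_mean: float = -6.8635      # kcal/mol of planted poses
    energy_sd: float = 0.0            # kcal/mol
    decoy_energy_offset: float = 2.0  # decoys are this much weaker (higher dG)
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF   # Å; jitter stays below half of it
    jitter: Optional[float] = None    # max RMSD of planted poses from the
                                      # reference geometry; default cutoff/2
    n_atoms: int = 10
    protein_id: str = "CSP1"
    ligand_id: str = "linoleic_acid"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_occupancy <= 1.0):
            raise ValueError("planted_occupancy must be in [0, 1]")
        if self.n_models < 1 or self.n_atoms < 1:
            raise ValueError("n_models and n_atoms must be >= 1")
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")
        if self.jitter is not None and not (0 <= self.jitter <= self.rmsd_cutoff / 2):
            raise ValueError("jitter must lie in [0, rmsd_cutoff/2]")


@dataclass(frozen=True)
class CtConfig:
    """Ct-table generator with prescribed per-sample fold changes."""

    fold_changes: Tuple[Tuple[str, float], ...] = (("adult", 8.0),)
    calibrator_sample: str = "egg"
    target_gene: str = "CSP1"
    reference_gene: str = "actin"
    n_replicates: int = 3
    reference_ct: float = 20.0        # cycles, reference-gene baseline
    calibrator_dct: float = 5.0       # cycles, target - reference in calibrator
    noise_sd: float = 0.0             # cycles, additive
    seed: int = 0

    def __post_init__(self) -> None:
        for sample, fold in self.fold_changes:
            if fold <= 0:
                raise ValueError(f"fold change for {sample!r} must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _concentrations(cmin: float, cmax: float, n: int, spacing: str) -> np.ndarray:
    if spacing == "log":
        return np.geomspace(cmin, cmax, n)
    if spacing == "linear":
        return np.linspace(cmin, cmax, n)
    raise ValueError(f"unknown spacing {spacing!r}")


def simulate_saturation(config: SaturationConfig) -> SaturationSeries:
    """Titration points on the one-site curve with multiplicative noise."""
    rng = np.random.default_rng(config.seed)
    conc = _concentrations(config.conc_min, config.conc_max,
                           config.n_points, config.spacing)
    ideal = saturation_intensity(conc, config.b_max, config.k_probe)
    noise = rng.normal(0.0, config.noise_sd, size=conc.shape) if config.noise_sd else 0.0
    intensity = np.clip(ideal * (1.0 + noise), 0.0, None)
    return SaturationSeries(protein_id=config.protein_id, probe_conc=conc,
                            intensity=intensity,
                            protein_conc=config.protein_conc)


def simulate_competition(config: CompetitionConfig) -> CompetitionSeries:
    """Log-spaced displacement curve from the competitive-binding model."""
    rng = np.random.default_rng(config.seed)
    conc = np.geomspace(config.conc_min, config.conc_max, config.n_points)
    ideal = competition_percent(conc, config.ki, config.probe_conc,
                                config.k_probe)
    noise = rng.normal(0.0, config.noise_sd, size=conc.shape) if config.noise_sd else 0.0
    percent = np.clip(ideal * (1.0 + noise), 0.0, 120.0)
    return CompetitionSeries(protein_id=config.protein_id,
                             ligand_id=config.ligand_id,
                             competitor_conc=conc,
                             percent_fluorescence=percent,
                             probe_conc=config.probe_conc)


def _jittered(reference: np.ndarray, max_rmsd: float,
              rng: np.random.Generator) -> np.ndarray:
    """Displace a geometry by a random perturbation of RMSD <= max_rmsd."""
    if max_rmsd <= 0:
        return reference.copy()
    disp = rng.normal(size=reference.shape)
    norm = np.sqrt(np.mean(np.sum(disp * disp, axis=1)))
    target = rng.uniform(0.0, max_rmsd)
    return reference + disp * (target / norm)


def simulate_pose_ensemble(config: EnsembleConfig) -> PoseEnsemble:
    """Ensemble with a planted consensus cluster of the requested occupancy.

    ``ceil(occupancy * n_models)`` randomly chosen models receive a pose
    jittered at most ``rmsd_cutoff/2`` around a shared reference geometry,
    energies drawn Normal(energy_mean, energy_sd); the remaining models
    receive decoys translated 3-6x the cutoff away with weaker energies.
    """
    rng = np.random.default_rng(config.seed)
    jitter = config.rmsd_cutoff / 2.0 if config.jitter is None else config.jitter
    reference = rng.uniform(-5.0, 5.0, size=(config.n_atoms, 3))
    n_planted = int(np.ceil(config.planted_occupancy * config.n_models))
    planted_models = set(rng.choice(config.n_models, size=n_planted,
                                    replace=False) + 1) if n_planted else set()

    poses: List[Pose] = []
    for model_id in range(1, config.n_models + 1):
        if model_id in planted_models:
            coords = _jittered(reference, jitter, rng)
            energy = (config.energy_mean
                      + (rng.normal(0.0, config.energy_sd) if config.energy_sd else 0.0))
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            distance = rng.uniform(3.5 * config.rmsd_cutoff,
                                   6.5 * config.rmsd_cutoff)
            # a rigid translation of the whole geometry shifts the RMSD by
            # exactly the translation length, keeping decoys >= 3x cutoff out
            coords = _jittered(reference + distance * direction, jitter, rng)
            energy = (config.energy_mean + config.decoy_energy_offset
                      + abs(rng.normal(0.0, 0.5)))
        poses.append(Pose(model_id=model_id, pose_index=1,
                          energy=float(energy), coords=coords))
    return PoseEnsemble(protein_id=config.protein_id,
                        ligand_id=config.ligand_id,
                        n_models=config.n_models, poses=poses)


def simulate_ct_table(config: CtConfig) -> List[CtRecord]:
    """Replicate Ct table realizing the configured fold changes.

    The reference (housekeeping) gene sits at its baseline — it is the
    assay's invariant endogenous control; the target gene sits
    ``calibrator_dct - log2(fold)`` cycles above that baseline with
    additive cycle noise, so the comparative-Ct analysis recovers each
    fold exactly at zero noise.  The calibrator sample (fold 1) is always
    included.
    """
    rng = np.random.default_rng(config.seed)
    folds: Dict[str, float] = {config.calibrator_sample: 1.0}
    folds.update(dict(config.fold_changes))

    records: List[CtRecord] = []
    for sample, fold in folds.items():
        target_base = config.reference_ct + config.calibrator_dct - np.log2(fold)
        for rep in range(1, config.n_replicates + 1):
            eps_t = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
            records.append(CtRecord(sample_id=sample,
                                    gene_id=config.reference_gene,
                                    replicate=rep,
                                    ct=float(config.reference_ct)))
            records.append(CtRecord(sample_id=sample,
                                    gene_id=config.target_gene,
                                    replicate=rep,
                                    ct=float(target_base + eps_t)))
    return records
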