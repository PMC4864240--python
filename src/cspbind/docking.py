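"""Consensus affinity from ensemble docking.

Docking one ligand against many homology models of the same receptor
(here, 100 models per chemosensory protein) yields a cloud of poses with
predicted binding free energies.  The consensus procedure is:

1. cluster all poses across models by ligand heavy-atom RMSD in the shared
   receptor frame (greedy, energy-ordered leader clustering);
2. select the cluster represented in the most models — the representative
   binding mode;
3. average the best per-model binding energies of that cluster;
4. convert the mean energy to a dissociation constant, Kd = exp(dG/RT)
   at T = 300 K;
5. weight Kd by free/bound, where *bound* is the number of models
   exhibiting the consensus pose and *free* the remainder.

Energies are kcal/mol, coordinates Å, Kd in mol/L (reported in μM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_RMSD_CUTOFF",
    "Pose",
    "PoseEnsemble",
    "PoseCluster",
    "ConsensusAffinity",
    "pose_rmsd",
    "cluster_poses",
    "select_representative",
    "aggregate_energy",
    "kd_from_energy",
    "energy_from_kd",
    "occupancy_weighted_kd",
    "consensus_pipeline",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3
DEFAULT_TEMPERATURE = 300.0   # K
DEFAULT_RMSD_CUTOFF = 2.0     # Å, common docking-pose clustering convention


@dataclass(eq=False)
class Pose:
    """One docked ligand placement: predicted dG and heavy-atom coordinates."""

    model_id: int
    pose_index: int
    energy: float                 # kcal/mol
    coords: np.ndarray            # (n_atoms, 3), Å, shared receptor frame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("pose needs at least one atom")
        if not math.isfinite(self.energy):
            raise ValueError("pose energy must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(eq=False)
class PoseEnsemble:
    """All poses of one ligand docked across an ensemble of receptor models."""

    protein_id: str
    ligand_id: str
    n_models: int
    poses: List[Pose]

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("ensemble must contain at least one pose")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        n_atoms = self.poses[0].n_atoms
        for p in self.poses:
            if p.n_atoms != n_atoms:
                raise ValueError("all poses must share atom count and order")
            if not (1 <= p.model_id <= self.n_models):
                raise ValueError(
                    f"model_id {p.model_id} outside [1, {self.n_models}]")


@dataclass(eq=False)
class PoseCluster:
    """A group of mutually similar poses with its seed as representative."""

    members: List[Pose]
    representative: Pose

    @property
    def models_represented(self) -> int:
        return len({p.model_id for p in self.members})

    @property
    def n_poses(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusAffinity:
    """Consensus binding mode summary for one protein-ligand pair."""

    protein_id: str
    ligand_id: str
    mean_energy: float        # kcal/mol, over best-per-model cluster energies
    sd_energy: float          # kcal/mol, sample sd (0 for a single model)
    kd: float                 # mol/L
    bound: int                # models exhibiting the consensus pose
    free: int                 # models not exhibiting it
    weighted_kd_uM: float     # μM, Kd scaled by free/bound
    degenerate: bool          # free == 0, weight taken as 1
    cluster_sizes: Tuple[int, ...] = ()   # models represented, per cluster

    @property
    def kd_uM(self) -> float:
        return self.kd * 1e6


def pose_rmsd(a: Pose, b: Pose) -> float:
    """Heavy-atom RMSD between two poses, without superposition.

    Poses from one ensemble share the receptor frame, so translating or
    rotating before comparison would erase binding-site placement
    differences.  Requires identical atom counts/order.
    """
    if a.coords.shape != b.coords.shape:
        raise ValueError(
            f"atom count mismatch: {a.coords.shape[0]} vs {b.coords.shape[0]}")
    diff = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def _energy_order(poses: Sequence[Pose]) -> List[int]:
    return sorted(range(len(poses)),
                  key=lambda i: (poses[i].energy, poses[i].model_id,
                                 poses[i].pose_index))


def cluster_poses(ensemble: PoseEnsemble,
                  rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF) -> List[PoseCluster]:
    """Greedy energy-ordered leader clustering of an ensemble's poses.

    Poses are visited by ascending energy (ties by model_id then
    pose_index); each unassigned pose seeds a cluster and absorbs every
    unassigned pose within ``rmsd_cutoff`` of it.  Deterministic; every
    pose assigned exactly once.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    poses = ensemble.poses
    order = _energy_order(poses)
    coords = np.stack([p.coords for p in poses])          # (n, A, 3)
    assigned = np.zeros(len(poses), dtype=bool)
    clusters: List[PoseCluster] = []
    for seed_idx in order:
        if assigned[seed_idx]:
            continue
        diff = coords - coords[seed_idx]
        rmsd = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
        member_mask = (~assigned) & (rmsd <= rmsd_cutoff)
        member_mask[seed_idx] = True
        members = [poses[i] for i in order if member_mask[i]]
        assigned |= member_mask
        clusters.append(PoseCluster(members=members,
                                    representative=poses[seed_idx]))
    return clusters


def select_representative(clusters: Sequence[PoseCluster],
                          by_models: bool = True) -> PoseCluster:
    """Pick the most populated cluster as the representative binding mode.

    Population is counted in distinct receptor models by default (the
    free/bound bookkeeping is per model); ``by_models=False`` counts raw
    poses instead.  Ties break by lower mean member energy, then lower
    representative energy; the choice is invariant to input order.
    """
    if not clusters:
        raise ValueError("no clusters to select from")

    def key(c: PoseCluster):
        population = c.models_represented if by_models else c.n_poses
        mean_e = float(np.mean([p.energy for p in c.members]))
        return (-population, mean_e, c.representative.energy,
                c.representative.model_id, c.representative.pose_index)

    return min(clusters, key=key)


def aggregate_energy(cluster: PoseCluster) -> Tuple[float, float]:
    """Mean and sample sd of the best per-model energies in a cluster.

    Using one (best) pose per represented model prevents models that
    contribute many near-duplicate poses from dominating the average.
    A single represented model yields sd 0.
    """
    if not cluster.members:
        raise ValueError("cluster is empty")
    best: dict[int, float] = {}
    for p in cluster.members:
        if p.model_id not in best or p.energy < best[p.model_id]:
            best[p.model_id] = p.energy
    values = np.array(sorted(best.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def kd_from_energy(mean_energy: float,
                   temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Dissociation constant Kd = exp(dG / RT) in mol/L.

    R = 1.9872e-3 kcal mol^-1 K^-1; strictly increasing in dG (more
    negative energy, tighter binding, smaller Kd).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(mean_energy / (GAS_CONSTANT_KCAL * temperature))


def energy_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`kd_from_energy`: dG = RT ln Kd (Kd in mol/L)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


def occupancy_weighted_kd(kd: float, bound: int, free: int) -> Tuple[float, bool]:
    """Weight Kd by the fraction free/bound of receptor models.

    With every model bound (free = 0) the literal weight would give an
    unphysical Kd of zero; the weight is then taken as 1 and the result
    flagged degenerate.
    """
    if bound < 1:
        raise ValueError("bound must be >= 1")
    if free < 0:
        raise ValueError("free must be >= 0")
    if free == 0:
        return kd, True
    return kd * free / bound, False


def consensus_pipeline(ensemble: PoseEnsemble,
                       rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
                       temperature: float = DEFAULT_TEMPERATURE,
                       by_models: bool = True) -> ConsensusAffinity:
    """Full consensus procedure: cluster, select, average, convert, weight."""
    clusters = cluster_poses(ensemble, rmsd_cutoff=rmsd_cutoff)
    rep = select_representative(clusters, by_models=by_models)
    bound = rep.models_represented
    free = ensemble.n_models - bound
    mean_e, sd_e = aggregate_energy(rep)
    kd = kd_from_energy(mean_e, temperature=temperature)
    weighted_kd_uM, degenerate = occupancy_weighted_kd(kd * 1e6, bound, free)
    sizes = tuple(sorted((c.models_represented for c in clusters), reverse=True))
    return ConsensusAffinity(protein_id=ensemble.protein_id,
                             ligand_id=ensemble.ligand_id,
                             mean_energy=mean_e, sd_energy=sd_e, kd=kd,
                             bound=bound, free=free,
                             weighted_kd_uM=weighted_kd_uM,
                             degenerate=degenerate, cluster_sizes=sizes)
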