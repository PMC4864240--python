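"""Unit tests for the ensemble-docking consensus stage."""

import math

import numpy as np
import pytest

from cspbind import (EnsembleConfig, GAS_CONSTANT_KCAL, Pose, PoseCluster,
                     PoseEnsemble, aggregate_energy, cluster_poses,
                     consensus_pipeline, energy_from_kd, kd_from_energy,
                     occupancy_weighted_kd, pose_rmsd, select_representative,
                     simulate_pose_ensemble)


def make_pose(model_id, coords, energy=-6.0, pose_index=1):
    return Pose(model_id=model_id, pose_index=pose_index, energy=energy,
                coords=np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# pose_rmsd
# ---------------------------------------------------------------------------

def test_rmsd_identity_and_translation():
    a = make_pose(1, [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
    assert pose_rmsd(a, a) == 0.0
    shifted = make_pose(2, a.coords + np.array([3.0, 0.0, 0.0]))
    assert pose_rmsd(a, shifted) == pytest.approx(3.0)


def test_rmsd_hand_calculation():
    a = make_pose(1, [[0, 0, 0], [1, 0, 0]])
    b = make_pose(2, [[0, 0, 0], [3, 0, 0]])
    assert pose_rmsd(a, b) == pytest.approx(math.sqrt(4.0 / 2.0))


def test_rmsd_atom_count_mismatch():
    a = make_pose(1, [[0, 0, 0]])
    b = make_pose(2, [[0, 0, 0], [1, 0, 0]])
    with pytest.raises(ValueError):
        pose_rmsd(a, b)


# ---------------------------------------------------------------------------
# cluster_poses
# ---------------------------------------------------------------------------

def _brute_force_check(ensemble, clusters, cutoff):
    """Oracle: leader-cluster invariants via exhaustive pairwise RMSDs."""
    seen = []
    for cluster in clusters:
        for member in cluster.members:
            assert pose_rmsd(member, cluster.representative) <= cutoff
            seen.append(id(member))
    assert sorted(seen) == sorted(id(p) for p in ensemble.poses)
    reps = [c.representative for c in clusters]
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            assert pose_rmsd(reps[i], reps[j]) > cutoff


def test_two_well_separated_groups_form_two_clusters():
    rng = np.random.default_rng(42)
    base = rng.uniform(-2, 2, size=(4, 3))
    group_a = [make_pose(m, base + rng.normal(0, 0.1, base.shape),
                         energy=-7 + 0.1 * m) for m in range(1, 7)]
    group_b = [make_pose(m, base + 10.0 + rng.normal(0, 0.1, base.shape),
                         energy=-5 + 0.1 * m, pose_index=2)
               for m in range(1, 7)]
    ensemble = PoseEnsemble("P", "L", n_models=6, poses=group_a + group_b)
    clusters = cluster_poses(ensemble, rmsd_cutoff=2.0)
    assert len(clusters) == 2
    sizes = sorted(c.n_poses for c in clusters)
    assert sizes == [6, 6]
    _brute_force_check(ensemble, clusters, 2.0)


def test_single_pose_is_singleton_cluster():
    ensemble = PoseEnsemble("P", "L", 1, [make_pose(1, [[0, 0, 0]])])
    clusters = cluster_poses(ensemble, 2.0)
    assert len(clusters) == 1 and clusters[0].n_poses == 1


def test_identical_coordinates_one_cluster():
    poses = [make_pose(m, [[1, 2, 3]], energy=-6 - m) for m in range(1, 6)]
    ensemble = PoseEnsemble("P", "L", 5, poses)
    clusters = cluster_poses(ensemble, 2.0)
    assert len(clusters) == 1 and clusters[0].n_poses == 5
    # seed is the lowest-energy pose
    assert clusters[0].representative.energy == min(p.energy for p in poses)


def test_cluster_rejects_nonpositive_cutoff():
    ensemble = PoseEnsemble("P", "L", 1, [make_pose(1, [[0, 0, 0]])])
    with pytest.raises(ValueError):
        cluster_poses(ensemble, 0.0)


# ---------------------------------------------------------------------------
# select_representative
# ---------------------------------------------------------------------------

def _cluster_of(n_models, energy, offset=0.0):
    members = [make_pose(m, [[offset, 0, 0]], energy=energy)
               for m in range(1, n_models + 1)]
    return PoseCluster(members=members, representative=members[0])


def test_select_most_models_wins():
    clusters = [_cluster_of(5, -6.0), _cluster_of(3, -8.0, 10),
                _cluster_of(2, -9.0, 20)]
    assert select_representative(clusters).models_represented == 5


def test_select_tie_broken_by_mean_energy():
    a = _cluster_of(4, -6.1)
    b = _cluster_of(4, -5.0, 10)
    assert select_representative([a, b]) is a
    assert select_representative([b, a]) is a  # order-invariant


def test_select_empty_raises():
    with pytest.raises(ValueError):
        select_representative([])


def test_select_by_pose_count_switch():
    many_poses = PoseCluster(
        members=[make_pose(1, [[0, 0, 0]], energy=-6, pose_index=i)
                 for i in range(1, 6)],
        representative=make_pose(1, [[0, 0, 0]], energy=-6))
    many_models = _cluster_of(3, -6.0, 10)
    assert select_representative([many_poses, many_models]) is many_models
    assert select_representative([many_poses, many_models],
                                 by_models=False) is many_poses


# ---------------------------------------------------------------------------
# aggregate_energy
# ---------------------------------------------------------------------------

def test_aggregate_single_member():
    cluster = _cluster_of(1, -6.0)
    assert aggregate_energy(cluster) == (-6.0, 0.0)


def test_aggregate_mean_and_sample_sd():
    members = [make_pose(m, [[0, 0, 0]], energy=e)
               for m, e in zip((1, 2, 3), (-6.0, -7.0, -8.0))]
    cluster = PoseCluster(members=members, representative=members[0])
    mean, sd = aggregate_energy(cluster)
    assert mean == pytest.approx(-7.0)
    assert sd == pytest.approx(1.0)


def test_aggregate_uses_best_pose_per_model():
    members = [make_pose(1, [[0, 0, 0]], energy=-6.2, pose_index=1),
               make_pose(1, [[0, 0, 0]], energy=-5.0, pose_index=2)]
    cluster = PoseCluster(members=members, representative=members[0])
    assert aggregate_energy(cluster) == (-6.2, 0.0)


# ---------------------------------------------------------------------------
# kd_from_energy / occupancy weighting
# ---------------------------------------------------------------------------

def test_kd_unit_cases():
    assert kd_from_energy(0.0) == 1.0
    rt = GAS_CONSTANT_KCAL * 300.0
    assert kd_from_energy(rt) == pytest.approx(math.e)
    assert kd_from_energy(-6.8635) * 1e6 == pytest.approx(10.0, rel=1e-3)


def test_kd_energy_round_trip():
    for kd in (1e-9, 1e-5, 0.5, 3.0):
        assert kd_from_energy(energy_from_kd(kd)) == pytest.approx(
            kd, rel=1e-12)


def test_kd_monotone_in_energy():
    energies = np.linspace(-12, 0, 25)
    kds = [kd_from_energy(e) for e in energies]
    assert all(a < b for a, b in zip(kds, kds[1:]))


@pytest.mark.parametrize("kd, bound, free, expected, degenerate", [
    (10.0, 50, 50, 10.0, False),
    (10.0, 80, 20, 2.5, False),
    (10.0, 100, 0, 10.0, True),
])
def test_weighted_kd_cases(kd, bound, free, expected, degenerate):
    value, flag = occupancy_weighted_kd(kd, bound, free)
    assert value == pytest.approx(expected)
    assert flag is degenerate


def test_weighted_kd_rejects_zero_bound():
    with pytest.raises(ValueError):
        occupancy_weighted_kd(10.0, 0, 5)


# ---------------------------------------------------------------------------
# consensus_pipeline
# ---------------------------------------------------------------------------

def test_pipeline_planted_cluster_worked_example():
    # 60% occupancy at dG = -6.8635 exactly: kd 10 uM, weighted 10 * 40/60
    ensemble = simulate_pose_ensemble(EnsembleConfig(
        n_models=10, planted_occupancy=0.6, energy_mean=-6.8635,
        energy_sd=0.0, jitter=0.0, seed=5))
    result = consensus_pipeline(ensemble, rmsd_cutoff=2.0)
    assert result.bound == 6 and result.free == 4
    assert result.kd_uM == pytest.approx(10.0, rel=1e-3)
    assert result.weighted_kd_uM == pytest.approx(result.kd_uM * 4 / 6)
    assert not result.degenerate


def test_pipeline_single_model_is_degenerate():
    ensemble = PoseEnsemble("P", "L", 1, [make_pose(1, [[0, 0, 0]],
                                                    energy=-6.8635)])
    result = consensus_pipeline(ensemble)
    assert result.bound == 1 and result.free == 0
    assert result.degenerate
    assert result.weighted_kd_uM == result.kd_uM


def test_pipeline_invariant_to_pose_order():
    config = EnsembleConfig(n_models=20, planted_occupancy=0.6,
                            energy_sd=0.4, seed=11)
    ensemble = simulate_pose_ensemble(config)
    reference = consensus_pipeline(ensemble)
    rng = np.random.default_rng(0)
    for _ in range(3):
        shuffled = list(ensemble.poses)
        rng.shuffle(shuffled)
        permuted = PoseEnsemble(ensemble.protein_id, ensemble.ligand_id,
                                ensemble.n_models, shuffled)
        result = consensus_pipeline(permuted)
        assert result.mean_energy == reference.mean_energy
        assert result.bound == reference.bound
        assert result.weighted_kd_uM == reference.weighted_kd_uM


def test_pipeline_invariant_to_model_relabeling():
    config = EnsembleConfig(n_models=12, planted_occupancy=0.5,
                            energy_sd=0.3, seed=7)
    ensemble = simulate_pose_ensemble(config)
    reference = consensus_pipeline(ensemble)
    relabel = {m: 13 - m for m in range(1, 13)}
    relabeled = PoseEnsemble(
        ensemble.protein_id, ensemble.ligand_id, ensemble.n_models,
        [Pose(relabel[p.model_id], p.pose_index, p.energy, p.coords.copy())
         for p in ensemble.poses])
    result = consensus_pipeline(relabeled)
    assert result.mean_energy == pytest.approx(reference.mean_energy)
    assert result.bound == reference.bound
    assert result.weighted_kd_uM == pytest.approx(reference.weighted_kd_uM)


def test_ensemble_invariants():
    with pytest.raises(ValueError):
        PoseEnsemble("P", "L", 1, [])
    with pytest.raises(ValueError):
        PoseEnsemble("P", "L", 2, [make_pose(3, [[0, 0, 0]])])
    with pytest.raises(ValueError):
        PoseEnsemble("P", "L", 2, [make_pose(1, [[0, 0, 0]]),
                                   make_pose(2, [[0, 0, 0], [1, 1, 1]])])
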