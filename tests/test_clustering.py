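"""Entity-level DBSCAN aggregation clustering against brute-force oracles."""

import numpy as np
import pytest

from cgkit.analysis import (ClusterParams, cluster_entities,
                            cluster_timeseries, entities_from_frame,
                            micelle_core_sizes)
from cgkit.fixtures import (make_disassembly_series, make_dispersed,
                            make_micelle, make_multicore_aggregate)
from cgkit.frames import Frame

from conftest import bead_cloud, brute_force_components, partitions_equal

PARAMS = ClusterParams(eps=8.0, min_samples=5)


def clustered_blobs(rng, n_blobs, per_blob, sep=30.0):
    """Frame of well-separated dense blobs of single-bead M1 entities."""
    pts = []
    for b in range(n_blobs):
        centre = np.array([b * sep, 0, 0], dtype=float)
        pts.append(centre + rng.uniform(-3, 3, size=(per_blob, 3)))
    return bead_cloud(np.vstack(pts))


def test_two_separated_micelle_groups_give_two_clusters(rng):
    frame = clustered_blobs(rng, 2, 10, sep=30.0)
    res = cluster_entities(frame, ClusterParams(entity="m1_sidechain"))
    assert res.n_clusters == 2
    assert sorted(res.sizes.values()) == [10, 10]
    # oracle agreement on the same instance
    _, members = entities_from_frame(frame, "m1_sidechain")
    oracle = brute_force_components(frame, members, 8.0, 5)
    assert partitions_equal(res.labels, oracle)


def test_dispersed_fixture_has_zero_clusters_all_noise():
    frame = make_dispersed(24, seed=3)
    res = cluster_entities(frame, PARAMS)
    assert res.n_clusters == 0
    assert np.all(res.labels == -1)


def test_single_aggregate_is_one_cluster():
    frame = make_multicore_aggregate(4, seed=9)
    res = cluster_entities(frame, PARAMS)
    assert res.n_clusters == 1
    assert res.largest == 40


def test_oracle_equivalence_on_many_constructed_instances(rng):
    # 50 instances with clean separation (no borderline chains)
    for trial in range(50):
        n_blobs = int(rng.integers(1, 5))
        per = int(rng.integers(5, 12))
        frame = clustered_blobs(rng, n_blobs, per, sep=40.0)
        for params in (ClusterParams(entity="m1_sidechain"),
                       ClusterParams(8.0, 5, "m1_sidechain")):
            res = cluster_entities(frame, params)
            _, members = entities_from_frame(frame, params.entity)
            oracle = brute_force_components(
                frame, members, params.eps, params.min_samples)
            assert partitions_equal(res.labels, oracle), f"trial {trial}"


def test_rigid_transformation_leaves_labels_unchanged(rng):
    frame = clustered_blobs(rng, 3, 8, sep=35.0)
    res0 = cluster_entities(frame, ClusterParams(entity="m1_sidechain"))
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = Frame(frame.coords @ rot.T + [5.0, -3.0, 11.0], frame.atoms)
    res1 = cluster_entities(moved, ClusterParams(entity="m1_sidechain"))
    assert partitions_equal(res0.labels, res1.labels)


def test_cluster_spanning_periodic_boundary_is_merged(rng):
    # dense blob straddling the box face: minimum-image metric must join it
    box = np.array([60.0, 60.0, 60.0])
    half = rng.uniform(-3, 3, size=(12, 3)) + [1.5, 30.0, 30.0]
    other = rng.uniform(-3, 3, size=(12, 3)) + [58.5, 30.0, 30.0]
    frame = bead_cloud(np.vstack([half, other]))
    frame = Frame(frame.coords, frame.atoms, box=box)
    res = cluster_entities(frame, ClusterParams(entity="m1_sidechain"))
    assert res.n_clusters == 1
    assert res.largest == 24


def test_stepwise_disassembly_series_recovers_largest_cluster_sizes():
    steps = [80, 60, 40, 20]
    traj = make_disassembly_series(steps, seed=11)
    table = cluster_timeseries(traj, PARAMS)
    assert list(table["largest"]) == steps
    # detached micelles each count as one extra cluster
    assert list(table["n_clusters"]) == [1, 2, 3, 4]


def test_timeseries_matches_framewise_clustering():
    traj = make_disassembly_series([40, 20], micelle_size=20, seed=2)
    table = cluster_timeseries(traj, PARAMS)
    for row, fr in zip(table.itertuples(), traj):
        res = cluster_entities(fr, PARAMS)
        assert row.n_clusters == res.n_clusters
        assert row.largest == res.largest


def test_constant_single_micelle_trajectory_stays_one_cluster():
    traj = [make_micelle(10, seed=4, time_ps=t * 100.0) for t in range(3)]
    table = cluster_timeseries(traj, PARAMS)
    assert list(table["n_clusters"]) == [1, 1, 1]


def test_micelle_core_size_histogram_matches_construction():
    frame = make_multicore_aggregate(core_sizes=[50, 200], seed=4)
    hist = micelle_core_sizes(frame)
    assert hist == {50: 1, 200: 1}
    single = make_multicore_aggregate(core_sizes=[60], seed=5)
    assert micelle_core_sizes(single) == {60: 1}


def test_core_size_histogram_equals_brute_force_components():
    frame = make_multicore_aggregate(core_sizes=[25, 40], seed=6)
    params = ClusterParams(entity="m1_sidechain")
    res = cluster_entities(frame, params)
    _, members = entities_from_frame(frame, "m1_sidechain")
    oracle = brute_force_components(frame, members, 8.0, 5)
    assert partitions_equal(res.labels, oracle)


def test_empty_inputs_rejected():
    import pandas as pd
    from cgkit.frames import ATOM_COLUMNS
    empty = Frame(np.zeros((0, 3)), pd.DataFrame(columns=ATOM_COLUMNS))
    with pytest.raises(ValueError, match="empty"):
        cluster_entities(empty, PARAMS)
    with pytest.raises(ValueError, match="empty"):
        cluster_timeseries([], PARAMS)
    with pytest.raises(ValueError):
        ClusterParams(eps=-1.0)
    with pytest.raises(ValueError):
        ClusterParams(min_samples=0)
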