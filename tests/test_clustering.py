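"""Two-stage clustering: descriptors, planted-basin recovery, profiles."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ffaudit import (
    ConfigurationSet,
    PredictionRecord,
    aggregate,
    cluster_configurations,
    cluster_error_profile,
    cluster_representatives,
    compute_error_table,
    distance_descriptor,
)


def _rigid_transform(positions, rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return positions @ q.T + rng.normal(size=3) * 10


# -- descriptor -------------------------------------------------------------

def test_descriptor_collinear_triple():
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    np.testing.assert_allclose(sorted(distance_descriptor(pos)), [1.0, 1.0, 2.0])


def test_descriptor_rigid_invariance(rng):
    pos = rng.normal(size=(8, 3))
    d1 = distance_descriptor(pos)
    d2 = distance_descriptor(_rigid_transform(pos, rng))
    np.testing.assert_allclose(d1, d2, atol=1e-10)


def test_descriptor_matches_double_loop_oracle(rng):
    pos = rng.normal(size=(5, 3))
    desc = distance_descriptor(pos)
    oracle = []
    for i in range(5):
        for j in range(i + 1, 5):
            oracle.append(np.sqrt(((pos[i] - pos[j]) ** 2).sum()))
    np.testing.assert_allclose(desc, oracle, atol=1e-12)


def test_descriptor_needs_two_atoms():
    with pytest.raises(ValueError):
        distance_descriptor(np.zeros((1, 3)))


# -- two-stage clustering ---------------------------------------------------

def _table_for(ds, rng, inflate_frames=None, factor=1.0):
    noise = rng.normal(scale=0.1, size=ds.forces.shape)
    if inflate_frames is not None:
        noise[inflate_frames] *= factor
    pred = PredictionRecord("p", ds.energies.copy(), ds.forces + noise)
    return compute_error_table(ds, pred)


def test_stage1_recovers_planted_basins_exactly(basin_ds, rng):
    table = _table_for(basin_ds, rng)
    assignment = cluster_configurations(
        basin_ds, table, n_total=3, n_structural=3, seed=0
    )
    truth = basin_ds.metadata["basin_labels"]
    assert adjusted_rand_score(truth, assignment.structural_labels) == 1.0


def test_stage1_invariant_under_rigid_motion(basin_ds, rng):
    table = _table_for(basin_ds, rng)
    a1 = cluster_configurations(basin_ds, table, n_total=3, n_structural=3, seed=0)
    moved = ConfigurationSet(
        atomic_numbers=basin_ds.atomic_numbers,
        positions=np.stack(
            [_rigid_transform(f, rng) for f in basin_ds.positions]
        ),
        energies=basin_ds.energies,
        forces=basin_ds.forces,
    )
    a2 = cluster_configurations(moved, table, n_total=3, n_structural=3, seed=0)
    assert adjusted_rand_score(a1.structural_labels, a2.structural_labels) == 1.0


def test_single_cluster_degenerate_equals_global_mae(basin_ds, rng):
    table = _table_for(basin_ds, rng)
    assignment = cluster_configurations(
        basin_ds, table, n_total=1, n_structural=1, seed=0
    )
    assert assignment.n_total == 1
    assert assignment.summaries[0]["size"] == basin_ds.n_frames
    assert assignment.summaries[0]["force_mae"] == pytest.approx(
        aggregate(table).mae, abs=1e-12
    )


def test_default_request_yields_forty_clusters(basin_ds, rng):
    # 90 frames is plenty of distinct frames for the default 40-cluster budget
    table = _table_for(basin_ds, rng)
    assignment = cluster_configurations(basin_ds, table, seed=0)
    assert assignment.n_total == 40
    assert np.unique(assignment.labels).size == 40


def test_fewer_distinct_frames_than_requested_warns(rng, caplog):
    pos = np.repeat(rng.normal(size=(3, 4, 3)), 5, axis=0)  # 15 frames, 3 distinct
    ds = ConfigurationSet(
        atomic_numbers=np.array([1, 1, 6, 8]),
        positions=pos,
        energies=np.repeat(rng.normal(size=3), 5),
        forces=np.zeros_like(pos),
    )
    with caplog.at_level("WARNING"):
        assignment = cluster_configurations(ds, None, n_total=10, n_structural=2)
    assert assignment.n_total == 3
    assert "distinct" in caplog.text


def test_size_weighted_cluster_maes_reproduce_global(basin_ds, rng):
    table = _table_for(basin_ds, rng)
    assignment = cluster_configurations(basin_ds, table, n_total=12, seed=0)
    weighted = sum(s["size"] * s["force_mae"] for s in assignment.summaries)
    assert weighted / basin_ds.n_frames == pytest.approx(
        aggregate(table).mae, abs=1e-12
    )


def test_large_set_subsampled_stage1_still_recovers_basins(rng):
    from ffaudit import FixtureSpec, generate_trajectory

    ds = generate_trajectory(
        FixtureSpec(formula="CH4", n_frames=240, n_basins=3,
                    basin_scale=2.5, thermal_scale=0.05, seed=3)
    )
    table = _table_for(ds, rng)
    assignment = cluster_configurations(
        ds, table, n_total=3, n_structural=3, seed=0, max_exact_frames=100
    )
    truth = ds.metadata["basin_labels"]
    assert adjusted_rand_score(truth, assignment.structural_labels) == 1.0


# -- profiles ---------------------------------------------------------------

def test_profile_all_zero_errors_ordered_by_id(basin_ds):
    pred = PredictionRecord("p", basin_ds.energies.copy(), basin_ds.forces.copy())
    table = compute_error_table(basin_ds, pred)
    assignment = cluster_configurations(
        basin_ds, table, n_total=6, n_structural=3, seed=0
    )
    profile = cluster_error_profile(assignment)
    assert [c for c, _, _ in profile] == list(range(6))
    assert all(v == 0.0 for _, _, v in profile)


def test_profile_inflated_cluster_ranks_last(basin_ds, rng):
    table = _table_for(basin_ds, rng)
    assignment = cluster_configurations(
        basin_ds, table, n_total=3, n_structural=3, seed=0
    )
    victim = assignment.labels[0]
    inflate = np.flatnonzero(assignment.labels == victim)
    table3 = _table_for(rng=np.random.default_rng(5), ds=basin_ds,
                        inflate_frames=inflate, factor=3.0)
    summaries = [
        {"size": int((assignment.labels == c).sum()),
         "force_mae": float(table3.atom_errors[assignment.labels == c].mean()),
         "energy_mae": None}
        for c in range(assignment.n_total)
    ]
    assignment.summaries = summaries
    profile = cluster_error_profile(assignment)
    assert profile[-1][0] == victim
    assert [v for _, _, v in profile] == sorted(v for _, _, v in profile)


# -- representatives --------------------------------------------------------

def test_representative_of_singleton_cluster(rng):
    ds = ConfigurationSet(
        atomic_numbers=np.array([1, 1]),
        positions=rng.normal(size=(4, 2, 3)),
        energies=rng.normal(size=4),
        forces=np.zeros((4, 2, 3)),
    )
    assignment = cluster_configurations(ds, None, n_total=4, n_structural=2, seed=0)
    reps = cluster_representatives(assignment, ds, k=3)
    for c, view in reps.items():
        assert len(view) == min(3, assignment.summaries[c]["size"])


def test_representative_matches_exhaustive_search(basin_ds, rng):
    table = _table_for(basin_ds, rng)
    assignment = cluster_configurations(
        basin_ds, table, n_total=5, n_structural=3, seed=0
    )
    reps = cluster_representatives(assignment, basin_ds, k=1)
    desc = assignment.descriptors
    for c, view in reps.items():
        members = np.flatnonzero(assignment.labels == c)
        centroid = desc[members].mean(axis=0)
        dists = [np.linalg.norm(desc[m] - centroid) for m in members]
        best = members[int(np.argmin(dists))]
        assert view.frame_indices[0] == best


def test_representative_tie_breaks_by_frame_index():
    # two frames mirror-symmetric about their descriptor centroid
    pos = np.zeros((2, 2, 3))
    pos[0, 1, 0] = 1.0
    pos[1, 1, 0] = 3.0
    ds = ConfigurationSet(
        atomic_numbers=np.array([1, 1]), positions=pos,
        energies=np.array([0.0, 0.0]), forces=np.zeros((2, 2, 3)),
    )
    assignment = cluster_configurations(ds, None, n_total=1, n_structural=1)
    reps = cluster_representatives(assignment, ds, k=1)
    assert reps[0].frame_indices[0] == 0
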