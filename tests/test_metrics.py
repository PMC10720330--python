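"""Error metrics against independent loop-based oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffaudit import (
    AtomSelection,
    ConfigurationSet,
    PredictionRecord,
    aggregate,
    compare_distributions,
    compute_error_table,
    correlation_scatter,
    kde,
    per_element_errors,
    relative_errors,
    timeline,
)
from ffaudit.synthetic import HALF_NORMAL_FACTOR


def _pair(rng, n_frames=5, n_atoms=4, z=(6, 1, 1, 8)):
    ds = ConfigurationSet(
        atomic_numbers=np.array(z),
        positions=rng.normal(size=(n_frames, n_atoms, 3)),
        energies=rng.normal(size=n_frames),
        forces=rng.normal(size=(n_frames, n_atoms, 3)),
    )
    pred = PredictionRecord(
        source_id="p",
        energies=ds.energies + rng.normal(size=n_frames),
        forces=ds.forces + rng.normal(size=(n_frames, n_atoms, 3)),
    )
    return ds, pred


# -- error table ------------------------------------------------------------

def test_identity_predictions_all_zero(tiny_ds, identity_pred):
    table = compute_error_table(tiny_ds, identity_pred)
    assert not table.atom_errors.any()
    assert not table.energy_errors.any()


def test_single_component_error_both_conventions():
    ds = ConfigurationSet(
        atomic_numbers=np.array([1]),
        positions=np.zeros((1, 1, 3)),
        energies=np.zeros(1),
        forces=np.zeros((1, 1, 3)),
    )
    pred = PredictionRecord(
        "p", energies=np.zeros(1), forces=np.array([[[0.3, 0.0, 0.0]]])
    )
    comp = compute_error_table(ds, pred, convention="component_mae")
    norm = compute_error_table(ds, pred, convention="vector_norm")
    assert comp.atom_errors[0, 0] == pytest.approx(0.1)
    assert norm.atom_errors[0, 0] == pytest.approx(0.3)


def test_error_table_matches_loop_oracle(rng):
    ds, pred = _pair(rng)
    table = compute_error_table(ds, pred, convention="component_mae")
    for f in range(ds.n_frames):
        for a in range(ds.n_atoms):
            expected = sum(
                abs(pred.forces[f, a, c] - ds.forces[f, a, c]) for c in range(3)
            ) / 3.0
            assert table.atom_errors[f, a] == pytest.approx(expected, abs=1e-10)
        assert table.energy_errors[f] == pytest.approx(
            pred.energies[f] - ds.energies[f], abs=1e-10
        )


# -- aggregation ------------------------------------------------------------

def test_element_weighted_mean_recombines_to_overall(rng):
    ds, pred = _pair(rng, n_frames=7)
    table = compute_error_table(ds, pred)
    overall = aggregate(table)
    weighted_mae = weighted_mse = total = 0.0
    for sym, samples in per_element_errors(table, ds).items():
        sel = AtomSelection.from_element(ds, sym)
        s = aggregate(table, atoms=sel)
        weighted_mae += s.mae * s.n
        weighted_mse += s.rmse**2 * s.n
        total += s.n
    assert weighted_mae / total == pytest.approx(overall.mae, abs=1e-12)
    assert np.sqrt(weighted_mse / total) == pytest.approx(overall.rmse, abs=1e-12)


def test_degenerate_single_atom_equal_components():
    ds = ConfigurationSet(
        atomic_numbers=np.array([1]),
        positions=np.zeros((1, 1, 3)),
        forces=np.zeros((1, 1, 3)),
        energies=np.zeros(1),
    )
    pred = PredictionRecord(
        "p", energies=np.zeros(1), forces=np.full((1, 1, 3), -0.2)
    )
    s = aggregate(compute_error_table(ds, pred))
    assert s.mae == pytest.approx(0.2) and s.rmse == pytest.approx(0.2)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(split=st.integers(min_value=1, max_value=3), seed=st.integers(0, 100))
def test_atom_partition_identity(split, seed):
    rng = np.random.default_rng(seed)
    ds, pred = _pair(rng)
    table = compute_error_table(ds, pred)
    left = AtomSelection.from_indices(range(split))
    right = AtomSelection.from_indices(range(split, ds.n_atoms))
    sl, sr = aggregate(table, atoms=left), aggregate(table, atoms=right)
    full = aggregate(table)
    assert (sl.mae * sl.n + sr.mae * sr.n) / (sl.n + sr.n) == pytest.approx(
        full.mae, abs=1e-12
    )
    assert np.sqrt((sl.rmse**2 * sl.n + sr.rmse**2 * sr.n) / (sl.n + sr.n)) == \
        pytest.approx(full.rmse, abs=1e-12)
    assert sl.rmse >= sl.mae and sr.rmse >= sr.mae


def test_empty_selection_raises(tiny_ds, identity_pred):
    table = compute_error_table(tiny_ds, identity_pred)
    with pytest.raises(ValueError, match="empty"):
        aggregate(table, atoms=AtomSelection.from_indices([]))


def test_frame_permutation_invariance(rng):
    ds, pred = _pair(rng, n_frames=6)
    perm = rng.permutation(6)
    ds2 = ConfigurationSet(
        atomic_numbers=ds.atomic_numbers,
        positions=ds.positions[perm],
        energies=ds.energies[perm],
        forces=ds.forces[perm],
    )
    pred2 = PredictionRecord("p", pred.energies[perm], pred.forces[perm])
    s1 = aggregate(compute_error_table(ds, pred))
    s2 = aggregate(compute_error_table(ds2, pred2))
    assert s1.mae == pytest.approx(s2.mae, abs=1e-12)
    assert s1.rmse == pytest.approx(s2.rmse, abs=1e-12)


# -- per-element and relative errors ---------------------------------------

def test_per_element_single_element_molecule(rng):
    ds, pred = _pair(rng, z=(1, 1, 1, 1))
    table = compute_error_table(ds, pred)
    samples = per_element_errors(table, ds)
    assert list(samples) == ["H"]
    assert samples["H"].size == ds.n_frames * ds.n_atoms


def test_per_element_sample_sizes_partition(rng):
    ds, pred = _pair(rng)
    table = compute_error_table(ds, pred)
    samples = per_element_errors(table, ds)
    assert sum(v.size for v in samples.values()) == ds.n_frames * ds.n_atoms


def test_per_element_planted_scale_ratio(planted_pair):
    ds, pred, em = planted_pair
    table = compute_error_table(ds, pred)
    samples = per_element_errors(table, ds)
    ratio = samples["C"].mean() / samples["H"].mean()
    assert ratio == pytest.approx(4.0, rel=0.05)
    # each mean matches the half-normal closed form E|N(0,s)| = s*sqrt(2/pi)
    assert samples["H"].mean() == pytest.approx(0.1 * HALF_NORMAL_FACTOR, rel=0.05)


def test_relative_errors_scale_invariance(rng):
    ds, pred = _pair(rng)
    table = compute_error_table(ds, pred)
    rel1 = relative_errors(table, ds)
    ds2 = ConfigurationSet(
        atomic_numbers=ds.atomic_numbers,
        positions=ds.positions,
        energies=ds.energies,
        forces=ds.forces * 2,
    )
    pred2 = PredictionRecord(
        "p", pred.energies, ds2.forces + 2 * (pred.forces - ds.forces)
    )
    rel2 = relative_errors(compute_error_table(ds2, pred2), ds2)
    for sym in rel1:
        np.testing.assert_allclose(rel1[sym], rel2[sym], rtol=1e-10)


def test_relative_errors_direct_ratio():
    ds = ConfigurationSet(
        atomic_numbers=np.array([6]),
        positions=np.zeros((1, 1, 3)),
        energies=np.zeros(1),
        forces=np.array([[[2.0, 0.0, 0.0]]]),
    )
    pred = PredictionRecord(
        "p", energies=np.zeros(1), forces=np.array([[[2.5, 0.0, 0.0]]])
    )
    table = compute_error_table(ds, pred, convention="vector_norm")
    assert relative_errors(table, ds)["C"][0] == pytest.approx(0.25)


def test_relative_errors_planted_equal_relative_scales(rng):
    # unequal absolute force scales, equal relative error -> equal relative MAEs
    n = 300
    z = np.array([1] * 3 + [6] * 3)
    forces = rng.normal(size=(n, 6, 3))
    forces[:, 3:] *= 5.0  # carbons feel 5x stronger forces
    ds = ConfigurationSet(
        atomic_numbers=z, positions=rng.normal(size=(n, 6, 3)),
        energies=np.zeros(n), forces=forces,
    )
    rel_scale = 0.1
    noise = rng.normal(size=forces.shape)
    noise[:, 3:] *= 5.0
    pred = PredictionRecord("p", np.zeros(n), forces + rel_scale * noise)
    rel = relative_errors(compute_error_table(ds, pred), ds)
    assert rel["H"].mean() == pytest.approx(rel["C"].mean(), rel=0.05)


# -- timeline ---------------------------------------------------------------

def test_timeline_window_one_is_identity(rng):
    x = rng.normal(size=20)
    np.testing.assert_array_equal(timeline(x, 1), x)


def test_timeline_constant_series_unchanged():
    np.testing.assert_allclose(timeline(np.full(9, 3.3), 5), np.full(9, 3.3))


def test_timeline_matches_loop_oracle(rng):
    x = rng.normal(size=31)
    w = 5
    out = timeline(x, w)
    half = w // 2
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        assert out[i] == pytest.approx(np.mean(x[lo:hi]), abs=1e-12)


def test_timeline_rejects_bad_window(rng):
    with pytest.raises(ValueError):
        timeline(rng.normal(size=5), 0)


# -- KDE --------------------------------------------------------------------

def test_kde_standard_normal_density_at_zero(rng):
    curve = kde(rng.normal(size=10000))
    at0 = np.interp(0.0, curve.grid, curve.density)
    assert at0 == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.10)


def test_kde_two_point_symmetry():
    curve = kde(np.array([0.0, 1.0]), bandwidth=0.1, n_grid=1001)
    mirrored = np.interp(1.0 - curve.grid[::-1], curve.grid, curve.density)
    np.testing.assert_allclose(curve.density[::-1], mirrored, atol=1e-9)


@pytest.mark.parametrize("n,bw", [(50, None), (500, 0.05), (2000, 1.3)])
def test_kde_integral_normalized(rng, n, bw):
    curve = kde(rng.normal(size=n) * 3, bandwidth=bw)
    assert 0.99 <= np.trapezoid(curve.density, curve.grid) <= 1.01


def test_kde_degenerate_samples_advise_histogram():
    with pytest.raises(ValueError, match="histogram"):
        kde(np.full(10, 2.0))


# -- correlation scatter ----------------------------------------------------

def test_scatter_perfect_correlation_no_flags(tiny_ds, identity_pred):
    sc = correlation_scatter(tiny_ds, identity_pred, "energy")
    assert not sc.flagged.any()


def test_scatter_planted_energy_outlier_flagged(rng):
    n = 200
    ds = ConfigurationSet(
        atomic_numbers=np.array([1]),
        positions=rng.normal(size=(n, 1, 3)),
        energies=rng.normal(size=n),
        forces=rng.normal(size=(n, 1, 3)),
    )
    sigma = 0.1
    e_pred = ds.energies + rng.normal(scale=sigma, size=n)
    e_pred[57] += 50 * sigma
    pred = PredictionRecord("p", e_pred, ds.forces.copy())
    sc = correlation_scatter(ds, pred, "energy")
    assert sc.outlier_indices.tolist() == [57]


def test_scatter_translation_invariance(rng):
    ds, pred = _pair(rng, n_frames=50)
    f1 = correlation_scatter(ds, pred, "energy").flagged
    ds2 = ConfigurationSet(
        atomic_numbers=ds.atomic_numbers, positions=ds.positions,
        energies=ds.energies + 100.0, forces=ds.forces,
    )
    pred2 = PredictionRecord("p", pred.energies + 100.0, pred.forces)
    np.testing.assert_array_equal(
        f1, correlation_scatter(ds2, pred2, "energy").flagged
    )


# -- distribution comparison ------------------------------------------------

def test_compare_identical_samples(rng):
    x = rng.normal(size=500)
    out = compare_distributions(x, x)
    assert out["histogram_intersection"] == pytest.approx(1.0)
    assert out["ks_statistic"] == pytest.approx(0.0)


def test_compare_disjoint_supports(rng):
    out = compare_distributions(rng.uniform(0, 1, 400), rng.uniform(5, 6, 400))
    assert out["histogram_intersection"] == 0.0


def test_compare_same_uniform_ks_below_critical(rng):
    n = 10000
    out = compare_distributions(rng.uniform(size=n), rng.uniform(size=n))
    crit_1pct = 1.628 * np.sqrt(2 / n)
    assert out["ks_statistic"] < crit_1pct


def test_compare_empty_raises(rng):
    with pytest.raises(ValueError):
        compare_distributions(np.array([]), rng.normal(size=3))
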