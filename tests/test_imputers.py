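import numpy as np
import pytest

from imputerank import (
    CellRef, NumericTable, apply_mask, default_registry, gen_two_linear_xy,
    impute_bagged_trees, impute_chained, impute_em_mvnorm, impute_knn,
    impute_mean, impute_median, impute_mode, impute_rf, impute_rsample,
    make_persistent_mask, missing_cells, run_method,
)
from imputerank.imputers import MethodSpec, half_sample_mode
from imputerank.seeding import child_seed


def table_with_missing(col, extra=None):
    """Two-column table: the given column plus a complete running index."""
    col = np.asarray(col, dtype=float)
    other = np.arange(len(col), dtype=float) if extra is None else np.asarray(extra, float)
    return NumericTable(np.column_stack([col, other]), col_ids=["v", "w"])


# ---------------------------------------------------------------------------
# univariate

def test_mean_fill():
    t = table_with_missing([1.0, 2.0, np.nan, 3.0])
    out = impute_mean(t)
    assert out.table.values[2, 0] == pytest.approx(2.0)
    assert not out.failed


def test_mean_complete_table_unchanged(small_table):
    assert impute_mean(small_table).table.equals(small_table)


def test_median_robust_to_outlier():
    t = table_with_missing([1.0, 2.0, 100.0, np.nan])
    assert impute_median(t).table.values[3, 0] == pytest.approx(2.0)


def test_mode_most_frequent_and_tie_to_smallest():
    t = table_with_missing([3.0, 3.0, 7.0, np.nan])
    assert impute_mode(t).table.values[3, 0] == 3.0
    t2 = table_with_missing([7.0, 7.0, 3.0, 3.0, np.nan])
    assert impute_mode(t2).table.values[4, 0] == 3.0


def test_half_sample_mode_concentrates():
    vals = np.concatenate([np.linspace(0, 10, 20), np.full(0, 0.0),
                           5.0 + 0.01 * np.arange(10)])
    assert 4.5 < half_sample_mode(vals) < 5.7


def test_rsample_support_property(rng):
    col = rng.normal(size=20)
    col[5] = np.nan
    t = table_with_missing(col)
    filled = impute_rsample(t, seed=3).table.values[5, 0]
    assert filled in set(col[~np.isnan(col)])


# ---------------------------------------------------------------------------
# kNN

def test_knn_duplicate_row_fills_exactly():
    vals = np.array([[1.0, 2.0, 3.0],
                     [1.0, 2.0, np.nan],
                     [9.0, 9.0, 9.0],
                     [5.0, 1.0, 0.0]])
    out = impute_knn(NumericTable(vals), k=1)
    assert out.table.values[1, 2] == pytest.approx(3.0)


def test_knn_noiseless_line_recovered():
    x = np.linspace(-1, 1, 40)
    vals = np.column_stack([x, x.copy()])
    vals[7, 1] = np.nan
    out = impute_knn(NumericTable(vals, col_ids=["x", "y"]), k=2)
    assert out.table.values[7, 1] == pytest.approx(x[7], abs=0.06)


def test_knn_clamps_k_to_donors():
    vals = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, np.nan], [4.0, 4.0]])
    out = impute_knn(NumericTable(vals), k=50)
    # all three donors averaged
    assert out.table.values[2, 1] == pytest.approx(np.mean([1, 2, 4]))


# ---------------------------------------------------------------------------
# chained equations

def test_chained_linear_recovers_collinear_data(rng):
    x = rng.uniform(-1, 1, 60)
    vals = np.column_stack([x, 2 * x + 1])
    vals[5, 1] = np.nan
    out = impute_chained(NumericTable(vals), model="linear", seed=0)
    # noiseless linear relation: residual sd ~ 0 so fill ~ exact
    assert out.table.values[5, 1] == pytest.approx(2 * x[5] + 1, abs=1e-6)


def test_pmm_support_property(rng):
    x = rng.uniform(-1, 1, 50)
    y = x + rng.normal(0, 0.1, 50)
    vals = np.column_stack([x, y])
    vals[3, 1] = np.nan
    out = impute_chained(NumericTable(vals), model="pmm", seed=1)
    observed = set(vals[~np.isnan(vals[:, 1]), 1])
    assert out.table.values[3, 1] in observed


def test_cart_step_structure(rng):
    x = np.concatenate([rng.uniform(-1, -0.2, 30), rng.uniform(0.2, 1, 30)])
    y = np.where(x < 0, 0.0, 10.0)
    vals = np.column_stack([x, y])
    vals[10, 1] = np.nan   # x < 0 plateau
    vals[45, 1] = np.nan   # x > 0 plateau
    out = impute_chained(NumericTable(vals), model="cart", seed=2)
    assert out.table.values[10, 1] == pytest.approx(0.0)
    assert out.table.values[45, 1] == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# forests / bagging / EM

@pytest.mark.parametrize("fn", [
    lambda t: impute_rf(t, variant="iterative", seed=1, n_trees=10),
    lambda t: impute_rf(t, variant="chained", seed=1, n_trees=10),
    lambda t: impute_bagged_trees(t, n_bags=10, seed=1),
    lambda t: impute_em_mvnorm(t, seed=1),
])
def test_complete_table_idempotence(fn, small_table):
    assert fn(small_table).table.equals(small_table)


@pytest.mark.parametrize("fn", [
    lambda t: impute_rf(t, variant="iterative", seed=7, n_trees=10),
    lambda t: impute_rf(t, variant="chained", seed=7, n_trees=10),
    lambda t: impute_bagged_trees(t, n_bags=10, seed=7),
    lambda t: impute_em_mvnorm(t, seed=7),
    lambda t: impute_chained(t, model="pmm", seed=7),
    lambda t: impute_rsample(t, seed=7),
])
def test_seed_determinism(fn, xy_table):
    masked, _ = apply_mask(xy_table, make_persistent_mask(xy_table, 0.1, seed=2))
    a, b = fn(masked), fn(masked)
    assert a.table.equals(b.table)


def test_em_reproduces_complete_data_moments(rng):
    from imputerank.imputers import em_mvnorm_fit
    X = rng.normal(size=(80, 3)) @ np.array([[1, 0.5, 0], [0, 1, 0.3], [0, 0, 1.0]])
    mu, sigma = em_mvnorm_fit(X)
    assert np.allclose(mu, X.mean(axis=0), atol=1e-8)
    assert np.allclose(sigma, np.cov(X.T, ddof=0), atol=1e-8)


def test_em_conditional_draws_close_to_truth_under_high_correlation(rng):
    """Bivariate normal with r = 0.99: a masked cell is imputed within 3
    conditional sd of the truth in nearly all seeds."""
    cov = np.array([[1.0, 0.99], [0.99, 1.0]])
    X = rng.multivariate_normal([0, 0], cov, size=300)
    cond_sd = np.sqrt(1 - 0.99**2)
    hits = 0
    n_seeds = 60
    for s in range(n_seeds):
        t = NumericTable(X.copy())
        truth = t.values[5, 1]
        t.values[5, 1] = np.nan
        out = impute_em_mvnorm(t, seed=s)
        if abs(out.table.values[5, 1] - truth) < 3.5 * cond_sd + 0.05:
            hits += 1
    assert hits >= n_seeds - 1


def test_multivariate_beats_mean_on_structured_data():
    """On the X-shaped generator with 10% masking, multivariate imputers
    outperform the column mean (paired over seeds, scale-free error)."""
    from imputerank.metrics import PairedValues, zdelta
    wins = {"knn5": 0, "rf": 0, "bag": 0}
    n_seeds = 6
    for s in range(n_seeds):
        t = gen_two_linear_xy(160, 0.05, seed=s)
        cells = make_persistent_mask(t, 0.1, seed=s)
        masked, truth = apply_mask(t, cells)
        sd = np.nanstd(t.values, axis=0, ddof=1)

        def mean_zd(outcome):
            cells_l = sorted(truth)
            tr = np.array([truth[c] for c in cells_l])
            im = np.array([outcome.table.values[c.row_index, c.col_index] for c in cells_l])
            s_of = np.array([sd[c.col_index] for c in cells_l])
            return np.mean(np.abs(im - tr) / s_of)

        base = mean_zd(impute_mean(masked))
        if mean_zd(impute_knn(masked, 5)) < base:
            wins["knn5"] += 1
        if mean_zd(impute_rf(masked, "iterative", seed=s, n_trees=15)) < base:
            wins["rf"] += 1
        if mean_zd(impute_bagged_trees(masked, n_bags=15, seed=s)) < base:
            wins["bag"] += 1
    assert all(w == n_seeds for w in wins.values())


# ---------------------------------------------------------------------------
# registry / dispatch

def test_registry_roster_and_categories():
    reg = default_registry()
    cats = {c: sum(1 for s in reg.values() if s.category == c)
            for c in ("univariate", "multivariate", "poisoned", "calibrating")}
    assert cats == {"univariate": 4, "multivariate": 18, "poisoned": 3,
                    "calibrating": 10}
    assert reg["pmm_repeated"].n_repeats == 20
    assert reg["tinyNoise_0.000001"].params["c"] == 1e-6
    assert reg["tinyNoise_1"].params["c"] == 1.0


def test_run_method_unknown_name_raises(small_table):
    with pytest.raises(KeyError):
        run_method(MethodSpec("nonesuch", "univariate"), small_table, 0)


def test_run_method_repeats_deterministic_equals_single(small_table):
    small_table.values[1, 1] = np.nan
    one = run_method(MethodSpec("median", "univariate"), small_table, 5)
    twenty = run_method(MethodSpec("median", "univariate", n_repeats=20), small_table, 5)
    assert one.table.equals(twenty.table)


def test_run_method_repeated_rsample_is_mean_of_replicates(small_table):
    small_table.values[2, 0] = np.nan
    spec = MethodSpec("rSample", "univariate", stochastic=True, n_repeats=20)
    out = run_method(spec, small_table, seed=9)
    draws = [
        impute_rsample(small_table, child_seed(9, "rSample", "rep", r)).table.values[2, 0]
        for r in range(20)
    ]
    assert out.table.values[2, 0] == pytest.approx(np.mean(draws), abs=1e-12)


def test_run_method_failure_keeps_na():
    """EM requires more rows than columns; failure is captured, not raised,
    and the masked cell stays missing."""
    vals = np.array([[1.0, 2.0, 3.0], [4.0, np.nan, 6.0], [7.0, 8.0, 9.0]])
    t = NumericTable(vals)
    out = run_method(MethodSpec("em_mvnorm", "multivariate"), t, 0)
    assert out.failed and out.failure_message
    assert missing_cells(out.table) == {CellRef(1, 1)}


def test_observed_cells_never_altered(xy_table):
    """No imputer touches an observed cell."""
    masked, _ = apply_mask(xy_table, make_persistent_mask(xy_table, 0.1, seed=4))
    obs = ~np.isnan(masked.values)
    reg = default_registry(n_trees=10)
    for name in ("mean", "median", "mode", "rSample", "knn3", "linear", "pmm",
                 "cart", "bag", "rf_chained", "rf_iterative", "em_mvnorm"):
        out = run_method(reg[name], masked, seed=1)
        assert not out.failed, name
        assert np.array_equal(out.table.values[obs], masked.values[obs]), name
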