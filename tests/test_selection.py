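import numpy as np
import pytest
from scipy import stats

from imputerank import (
    abc_score, aggregate_ranks, cabc_categorize, compare_uni_multi,
    dts_statistic, rank_slice, select_best, standardize_rank,
)
from imputerank.selection import RankCube


# ---------------------------------------------------------------------------
# ranking

def test_rank_slice_tie_averaging():
    assert list(rank_slice([0.1, 0.3, 0.1])) == [1.5, 3.0, 1.5]


def test_rank_slice_all_gated_away():
    assert list(rank_slice([0.0, 0.0, 0.0, 0.0])) == [2.5] * 4


def test_rank_slice_failure_forced_to_bottom():
    ranks = rank_slice([0.5, 0.1, 0.0], failed=[False, False, True])
    assert list(ranks) == [2.0, 1.0, 3.0]


def make_cube(rng, M=6, V=3, k=4):
    ranks = np.empty((M, V, k, 3))
    for v in range(V):
        for j in range(k):
            for met in range(3):
                ranks[:, v, j, met] = rank_slice(rng.random(M))
    return RankCube([f"m{i}" for i in range(M)], ranks)


def test_aggregate_ranks_matches_triple_loop_oracle(rng):
    for _ in range(10):
        cube = make_cube(rng)
        R = aggregate_ranks(cube)
        M, V, k, _ = cube.ranks.shape
        for mi, name in enumerate(cube.methods):
            acc = 0.0
            for v in range(V):
                for j in range(k):
                    acc += cube.ranks[mi, v, j, :].sum() / 3.0
            assert R[name] == pytest.approx(acc / (V * k), abs=1e-12)


def test_aggregate_constant_winner():
    ranks = np.tile(np.arange(1.0, 5.0)[:, None, None, None], (1, 2, 3, 3))
    cube = RankCube(["a", "b", "c", "d"], ranks)
    assert aggregate_ranks(cube)["a"] == 1.0


def test_aggregate_permutation_invariance(rng):
    cube = make_cube(rng)
    perm = rng.permutation(cube.ranks.shape[1])
    cube2 = RankCube(cube.methods, cube.ranks[:, perm])
    a, b = aggregate_ranks(cube), aggregate_ranks(cube2)
    assert all(a[m] == pytest.approx(b[m], abs=1e-12) for m in a)


# ---------------------------------------------------------------------------
# standardization and ABC scores

def test_standardize_midpoint_is_zero():
    Z, p = standardize_rank(15.0, M=29, d=20)
    assert Z == 0.0 and p == 0.5


def test_standardize_known_value():
    Z, _ = standardize_rank(13.0, M=29, d=20)
    assert Z == pytest.approx(-2.0 / (29.0 / np.sqrt(240.0)), abs=1e-9)
    assert Z == pytest.approx(-1.0684, abs=1e-4)


def test_standardize_corrected_variance_switch():
    Z, _ = standardize_rank(13.0, M=29, d=20, corrected=True)
    assert Z == pytest.approx(-2.0 / np.sqrt((29**2 - 1) / 240.0), abs=1e-9)


def test_abc_score_branches():
    assert abc_score(-2.0) == 4.0
    assert abc_score(1.0) == 0.0
    assert abc_score(0.0) == 0.0


def test_cabc_dominant_item():
    scores = {"a": 9.0, "b": 0.1, "c": 0.1, "d": 0.1, "e": 0.0}
    cats, _ = cabc_categorize(scores)
    assert cats["a"] == "A"
    assert all(cats[k] == "C" for k in "bcde")


def test_cabc_two_equal_positives_with_zeros():
    cats, _ = cabc_categorize({"a": 4.0, "b": 4.0, "c": 0.0, "d": 0.0})
    assert cats["a"] == "A" and cats["b"] == "A"
    assert cats["c"] == "C" and cats["d"] == "C"


def test_cabc_all_equal_degenerate_rule():
    cats, _ = cabc_categorize({"a": 2.0, "b": 2.0, "c": 2.0, "d": 2.0})
    assert sorted(cats.values()).count("A") == 1
    assert cats["a"] == "A"  # name order breaks the tie


def test_cabc_all_zero_warns():
    cats, warnings = cabc_categorize({"a": 0.0, "b": 0.0, "c": 0.0})
    assert set(cats.values()) == {"C"} and warnings


def test_cabc_a_is_prefix_and_rescaling_invariant(rng):
    for _ in range(20):
        scores = {f"m{i}": float(v) for i, v in enumerate(rng.gamma(1.0, 2.0, 8))}
        cats, _ = cabc_categorize(scores)
        order = sorted(scores, key=lambda k: (-scores[k], k))
        labels = [cats[k] for k in order]
        assert "".join(labels) == "".join(sorted(labels, key="ABC".index))
        assert "A" in labels
        scaled, _ = cabc_categorize({k: 7.3 * v for k, v in scores.items()})
        assert scaled == cats


# ---------------------------------------------------------------------------
# winner selection

CATS = {"good": "univariate", "better": "multivariate", "plus": "poisoned",
        "noise": "calibrating"}


def test_select_best_unique_minimum():
    R = {"good": 3.0, "better": 2.0, "plus": 1.0, "noise": 0.5}
    best, warnings = select_best(R, {"plus": "A"}, CATS)
    assert best == "better"  # references never selectable
    assert any("not advisable" in w for w in warnings)


def test_select_best_tie_broken_by_rmsd_then_name():
    R = {"good": 2.0, "better": 2.0, "plus": 9.0, "noise": 9.0}
    best, _ = select_best(R, {}, CATS, mean_raw_rmsd={"good": 0.1, "better": 0.5})
    assert best == "good"
    best, _ = select_best(R, {}, CATS, mean_raw_rmsd={"good": 0.5, "better": 0.5})
    assert best == "better"  # alphabetical


def test_select_best_no_eligible_raises():
    with pytest.raises(ValueError):
        select_best({"plus": 1.0}, {}, {"plus": "poisoned"})


# ---------------------------------------------------------------------------
# two-sample comparison

def test_dts_identical_samples_zero():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert dts_statistic(x, x) == 0.0
    p_dts, p_w, p_f = compare_uni_multi(x, x, n_permutations=200, seed=1)
    assert p_dts >= 0.5


def test_fisher_combination_values():
    # p = (1, 1): X2 = 0 -> combined p = 1
    p_dts, p_w, p_f = compare_uni_multi([2.0] * 6, [2.0] * 6, seed=0)
    assert (p_dts, p_w, p_f) == (1.0, 1.0, 1.0)
    # chi-square(4) upper tail at X2 = -2(ln .05 + ln .05)
    x2 = -2 * (np.log(0.05) + np.log(0.05))
    assert stats.chi2.sf(x2, 4) == pytest.approx(0.0175, abs=5e-4)


def test_compare_separated_samples_significant(rng):
    x = rng.normal(0.0, 0.2, 40)
    y = rng.normal(2.0, 0.2, 40)
    p_dts, p_w, p_f = compare_uni_multi(x, y, n_permutations=500, seed=3)
    assert p_dts < 0.05 and p_w < 1e-6 and p_f < 1e-3


def test_compare_requires_min_samples():
    with pytest.raises(ValueError):
        compare_uni_multi([1, 2, 3], [1, 2, 3, 4, 5])


# ---------------------------------------------------------------------------
# null calibration

def test_null_calibration_mean_z_near_zero(rng):
    """With equal-quality methods, the mean standardized rank across methods
    is ~0 and few methods reach category A."""
    M, V, k = 30, 3, 5  # registry-sized method roster
    mean_zs, frac_a = [], []
    for _ in range(50):
        cube = make_cube(rng, M=M, V=V, k=k)
        R = aggregate_ranks(cube)
        Z = {m: standardize_rank(R[m], M, V * k)[0] for m in R}
        mean_zs.append(np.mean(list(Z.values())))
        cats, _ = cabc_categorize({m: abc_score(z) for m, z in Z.items()})
        frac_a.append(np.mean([c == "A" for c in cats.values()]))
    assert abs(np.mean(mean_zs)) < 0.2
    # with the distance-to-(0,1) boundary roughly a fifth of equal-quality
    # methods land in A by chance
    assert np.mean(frac_a) <= 0.25
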