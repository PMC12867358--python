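"""Rank aggregation, standardization, computed-ABC categorization and winner
selection.

For every (variable, iteration, metric) slice the methods are ranked
ascending on the gated metric (tie-averaged; failed methods are forced to
the bottom).  A method's overall score is the mean rank over all metrics,
variables and iterations.  Treating the mean of d = V*k i.i.d. uniform
ranks as Irwin–Hall and hence approximately Gaussian with mean
``m = (M + 1)/2`` and spread ``s = M / sqrt(12 d)``, the standardized rank
``Z = (R - m)/s`` and its Gaussian tail probability situate every method;
negative-Z methods receive an ABC score ``Z^2`` and are split by computed
ABC analysis into the important few (A), the acceptable (B) and the trivial
many (C).  Reference methods compete in the ranking (so a poisoned method
surfacing in A flags non-imputability) but are never selectable as winner;
the calibrating tinyNoise ladder is reported separately and excluded from
categorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seeding import child_seed

__all__ = [
    "RankCube", "SelectionResult", "rank_slice", "aggregate_ranks",
    "standardize_rank", "abc_score", "cabc_categorize", "select_best",
    "dts_statistic", "compare_uni_multi",
]


@dataclass
class RankCube:
    """Ranks indexed by (method, variable, iteration, metric); NaN marks a
    slice that produced no diagnostic cells and was skipped."""

    methods: list[str]
    ranks: np.ndarray  # shape (M, V, k, 3)

    @property
    def n_methods(self) -> int:
        return len(self.methods)

    @property
    def d_effective(self) -> int:
        """Number of (variable, iteration) slices actually ranked."""
        present = ~np.isnan(self.ranks[0, :, :, 0])
        return int(present.sum())


@dataclass
class SelectionResult:
    R: dict[str, float]
    Z: dict[str, float]
    p: dict[str, float]
    abc_score: dict[str, float]
    category: dict[str, str]
    best_method: str
    warnings: list[str] = field(default_factory=list)
    M: int = 0
    d: int = 0


def rank_slice(values, failed=None) -> np.ndarray:
    """Ascending tie-averaged ranks of one metric slice across methods.

    Failed methods (or NaN values) are forced to the bottom; ties among
    them are averaged among themselves.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 methods to rank")
    v = v.copy()
    if failed is not None:
        v[np.asarray(failed, dtype=bool)] = np.inf
    v[np.isnan(v)] = np.inf
    return stats.rankdata(v, method="average")


def aggregate_ranks(cube: RankCube) -> dict[str, float]:
    """Mean over variables and iterations of the three metrics' mean rank."""
    per_slice = cube.ranks.mean(axis=3)          # (M, V, k): mean over metrics
    with np.errstate(invalid="ignore"):
        R = np.nanmean(per_slice.reshape(cube.n_methods, -1), axis=1)
    return {m: float(r) for m, r in zip(cube.methods, R)}


def standardize_rank(R: float, M: int, d: int, corrected: bool = False) -> tuple[float, float]:
    """Standardized average rank and its Gaussian tail probability.

    ``s = M / sqrt(12 d)`` as printed in the framework's derivation; with
    ``corrected=True`` the exact variance of a mean of d uniform ranks,
    ``sqrt((M^2 - 1) / (12 d))``, is used instead.
    """
    if M < 2 or d < 1:
        raise ValueError("need M >= 2 and d >= 1")
    m = (M + 1) / 2.0
    s = np.sqrt((M**2 - 1) / (12.0 * d)) if corrected else M / np.sqrt(12.0 * d)
    Z = (R - m) / s
    return float(Z), float(stats.norm.cdf(Z))


def abc_score(Z: float) -> float:
    """ABC score: ``Z^2`` for ``Z < 0``, else 0 (only better-than-average
    methods accrue importance)."""
    return float(Z * Z) if Z < 0 else 0.0


def cabc_categorize(scores: dict[str, float]) -> tuple[dict[str, str], list[str]]:
    """Computed-ABC split of descending scores into A / B / C.

    The cumulative-contribution curve is built over items sorted by
    descending score; the A|B boundary is the curve point closest to the
    ideal (0, 1), the B|C boundary the last point before the discrete slope
    first falls to <= 1.  Zero-score items are always C.  When all scores
    are equal and positive (a flat curve of unit slopes) the degenerate rule
    assigns only the first item to A.
    """
    warnings: list[str] = []
    if len(scores) < 3:
        raise ValueError("cABC needs at least 3 items")
    items = sorted(scores, key=lambda k: (-scores[k], k))
    vals = np.array([scores[k] for k in items], dtype=float)
    if (vals < 0).any():
        raise ValueError("scores must be nonnegative")
    total = vals.sum()
    if total == 0:
        warnings.append("all ABC scores are zero; no method stands out")
        return {k: "C" for k in items}, warnings
    n = len(items)
    pos = vals > 0
    if pos.all() and np.allclose(vals, vals[0], rtol=1e-12, atol=0.0):
        i_ab = 1  # degenerate flat curve: all discrete slopes equal 1
    else:
        x = np.arange(1, n + 1) / n
        y = np.cumsum(vals) / total
        dist2 = x**2 + (1.0 - y) ** 2
        i_ab = int(np.argmin(dist2)) + 1          # 1-based boundary item
    slopes = n * vals / total
    below = np.flatnonzero(slopes <= 1.0)
    i_bc = int(below[0]) if below.size else n     # last item before break-even
    i_bc = max(i_ab, i_bc)
    cats: dict[str, str] = {}
    for idx, k in enumerate(items, start=1):
        if vals[idx - 1] == 0:
            cats[k] = "C"
        elif idx <= i_ab:
            cats[k] = "A"
        elif idx <= i_bc:
            cats[k] = "B"
        else:
            cats[k] = "C"
    return cats, warnings


def select_best(
    R: dict[str, float],
    categories: dict[str, str],
    method_category: dict[str, str],
    mean_raw_rmsd: dict[str, float] | None = None,
    eligible_categories: frozenset = frozenset({"univariate", "multivariate"}),
) -> tuple[str, list[str]]:
    """Winner = argmin of the mean rank among genuine methods; ties broken by
    lower mean raw RMSD, then name.  Reference methods are never selectable;
    a poisoned method in category A adds a non-imputability warning."""
    eligible = [m for m in R if method_category.get(m) in eligible_categories]
    if not eligible:
        raise ValueError("no eligible methods to select from")
    rmsd_of = mean_raw_rmsd or {}

    def key(m):
        return (R[m], rmsd_of.get(m, np.inf), m)

    best = min(eligible, key=key)
    warnings = []
    poisoned_in_a = sorted(
        m for m, c in categories.items()
        if c == "A" and method_category.get(m) == "poisoned"
    )
    if poisoned_in_a:
        warnings.append(
            "imputation not advisable: poisoned method(s) in category A: "
            + ", ".join(poisoned_in_a)
        )
    return best, warnings


# ---------------------------------------------------------------------------
# best-univariate vs best-multivariate comparison

def dts_statistic(x, y) -> float:
    """Weighted ECDF-distance statistic between two samples.

    Sums ``|ECDF_x(t) - ECDF_y(t)| / sqrt(t (1 - t))`` over the pooled order
    statistics, where ``t`` is the pooled ECDF height (endpoints with
    ``t (1 - t) = 0`` excluded); sensitive to both location and tail
    differences.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pooled = np.sort(np.concatenate([x, y]))
    n = pooled.size
    f1 = np.searchsorted(x, pooled, side="right") / x.size
    f2 = np.searchsorted(y, pooled, side="right") / y.size
    t = np.arange(1, n + 1) / n
    keep = (t > 0) & (t < 1)
    return float((np.abs(f1 - f2)[keep] / np.sqrt(t[keep] * (1 - t[keep]))).sum())


def compare_uni_multi(
    zdeltas_best_uni,
    zdeltas_best_multi,
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Compare the zDelta distributions of the best univariate and best
    multivariate methods: seeded-permutation p of the weighted ECDF-distance
    statistic, two-sided Wilcoxon rank-sum p, and their Fisher combination
    (chi-square with 4 degrees of freedom)."""
    x = np.asarray(zdeltas_best_uni, dtype=float)
    y = np.asarray(zdeltas_best_multi, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("both samples need length >= 5")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        p_dts = p_w = 1.0
    else:
        obs = dts_statistic(x, y)
        rng = np.random.default_rng(child_seed(seed, "dts"))
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if dts_statistic(perm[: x.size], perm[x.size:]) >= obs:
                hits += 1
        p_dts = (hits + 1) / (n_permutations + 1)
        p_w = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    x2 = -2.0 * (np.log(p_dts) + np.log(p_w))
    p_fisher = float(stats.chi2.sf(x2, df=4))
    return float(p_dts), p_w, p_fisher
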