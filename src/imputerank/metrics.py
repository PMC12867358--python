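"""Robust imputation-quality metrics with significance gating.

Per (method, variable, iteration) the framework scores the imputed values
``y'`` against the saved truth ``y`` with three robust, lower-is-better
metrics:

* RMSD  — root median square deviation, ``sqrt(median((y' - y)^2))``;
* MD    — absolute median difference, ``|median(y' - y)|`` (systematic
  over-/under-estimation);
* rBias — absolute Theil–Sen slope of the difference ``d = y' - y`` on the
  pair mean ``m = (y' + y)/2`` (Bland–Altman-style value-dependent bias).

Before ranking, each metric is *gated*: it is set to zero when its deviation
from zero is not significant at ``p >= 0.1`` — RMSD and MD by a two-sided
one-sample Wilcoxon signed-rank test of ``d`` against zero (exact null
distribution for n <= 25, normal approximation with continuity and tie
correction above), rBias by the two-sided Kendall-tau association test
between ``d`` and ``m``.  Gating prevents negligible differences from
driving the method order.

The scale-free accuracy zDelta is the mean absolute difference between
z-scored truth and imputation, ``mean|y' - y| / s`` with ``m``/``s`` taken
from the complete pre-masking column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedValues", "MetricRecord", "rmsd", "md", "rbias", "gate", "zdelta",
    "signed_rank_p", "GATE_ALPHA",
]

GATE_ALPHA = 0.1  # printed gating threshold; overridable per run


@dataclass
class PairedValues:
    """Aligned truth/imputed value pairs for one (variable, iteration)."""

    truth: np.ndarray
    imputed: np.ndarray
    variable: str = ""
    iteration: int = 0

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=float)
        if self.truth.shape != self.imputed.shape or self.truth.ndim != 1:
            raise ValueError("truth and imputed must be equal-length 1-D arrays")
        if self.truth.size < 1:
            raise ValueError("paired values must be nonempty")

    @property
    def diffs(self) -> np.ndarray:
        return self.imputed - self.truth

    @property
    def means(self) -> np.ndarray:
        return (self.imputed + self.truth) / 2.0


@dataclass
class MetricRecord:
    rmsd: float
    md: float
    rbias: float
    p_rmsd: float
    p_md: float
    p_rbias: float
    gated_rmsd: float
    gated_md: float
    gated_rbias: float
    zdelta: float = float("nan")


def rmsd(pairs: PairedValues) -> float:
    """Root median square deviation of imputed vs true values."""
    d = pairs.diffs
    return float(np.sqrt(np.median(d * d)))


def md(pairs: PairedValues) -> float:
    """Absolute value of the median imputed-minus-true difference."""
    return float(abs(np.median(pairs.diffs)))


def rbias(pairs: PairedValues) -> float:
    """Absolute Theil–Sen slope of d on the Bland–Altman pair mean; 0 when
    the pair means are all identical or fewer than 3 pairs are available."""
    if pairs.truth.size < 3:
        return 0.0
    m = pairs.means
    if np.all(m == m[0]):
        return 0.0
    slope = stats.theilslopes(pairs.diffs, m).slope
    return float(abs(slope))


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank two-sided p (handles ties via doubled ranks)

def _exact_signed_rank_p(d: np.ndarray) -> float:
    n = d.size
    ranks = stats.rankdata(np.abs(d))           # tie-averaged, so 2*rank is integer
    iranks = np.rint(2.0 * ranks).astype(int)
    w = int(iranks[d > 0].sum())                # observed doubled W+
    total = int(iranks.sum())
    # distribution of W+ over the 2^n equiprobable sign assignments, by DP
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in iranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0**n
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_signed_rank_p(d: np.ndarray) -> float:
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def signed_rank_p(diffs: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value of ``diffs`` vs 0.

    Zeros are dropped (Wilcoxon's rule); all-zero differences give p = 1.
    Exact null distribution (sign enumeration, tie-aware) for n <= 25,
    normal approximation with continuity correction above.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    if d.size <= exact_max_n:
        return _exact_signed_rank_p(d)
    return _approx_signed_rank_p(d)


def _kendall_p(pairs: PairedValues) -> float:
    if pairs.truth.size < 3:
        return 1.0
    d, m = pairs.diffs, pairs.means
    if np.all(d == d[0]) or np.all(m == m[0]):
        return 1.0
    res = stats.kendalltau(m, d)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def gate(value: float, pairs: PairedValues, which: str, alpha: float = GATE_ALPHA) -> tuple[float, float]:
    """Zero a metric whose deviation from zero is not significant.

    Returns ``(gated_value, p)`` with ``gated_value = value`` when
    ``p < alpha`` and 0 otherwise.
    """
    which = which.upper()
    if which == "RMSD":
        # error magnitude: test the absolute deviations against zero, so a
        # method with large but sign-balanced errors cannot escape the gate
        p = signed_rank_p(np.abs(pairs.diffs))
    elif which == "MD":
        p = signed_rank_p(pairs.diffs)
    elif which == "RBIAS":
        p = _kendall_p(pairs)
    else:
        raise ValueError(f"unknown metric {which!r}")
    return (value if p < alpha else 0.0), p


def zdelta(pairs: PairedValues, column_mean: float, column_sd: float) -> float:
    """Scale-free accuracy: mean absolute difference of z-scored values.

    ``column_mean``/``column_sd`` come from the complete (pre-masking)
    column; the mean cancels, so this equals ``mean|y' - y| / s``.
    """
    if not column_sd > 0:
        raise ValueError("column standard deviation must be positive")
    return float(np.mean(np.abs(pairs.imputed - pairs.truth)) / column_sd)


def evaluate_pairs(pairs: PairedValues, column_mean: float, column_sd: float,
                   alpha: float = GATE_ALPHA) -> MetricRecord:
    """All three gated metrics plus zDelta for one (variable, iteration)."""
    r, b = rmsd(pairs), md(pairs)
    s = rbias(pairs)
    gr, pr = gate(r, pairs, "RMSD", alpha)
    gm, pm = gate(b, pairs, "MD", alpha)
    gs, ps = gate(s, pairs, "RBIAS", alpha)
    if pairs.truth.size < 3:
        gs, ps = 0.0, 1.0
    zd = zdelta(pairs, column_mean, column_sd)
    return MetricRecord(r, b, s, pr, pm, ps, gr, gm, gs, zd)
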