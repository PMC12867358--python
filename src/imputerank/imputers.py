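"""Imputation methods and the method registry.

Univariate methods use only the incomplete column itself (mean, median,
mode, random resampling); multivariate methods exploit cross-variable
structure (k-nearest neighbours, chained-equations regression with linear /
predictive-mean-matching / regression-tree models, bagged trees, iterative
and chained random forests, and EM-based multivariate-normal multiple
imputation).  Stochastic methods carry ``_repeated`` variants whose result
is the cell-wise mean of 20 seeded replicates.

Every method is invoked through one uniform signature and returns an
:class:`ImputationOutcome`; an exception inside a method is captured as a
failed outcome whose masked cells remain missing, so the selection stage
can penalise unsuccessful methods instead of aborting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .references import DEFAULT_C, TINYNOISE_GRID, fill_reference
from .seeding import child_seed
from .tabular import CellRef, NumericTable

__all__ = [
    "MethodSpec", "ImputationOutcome", "default_registry", "run_method",
    "impute_mean", "impute_median", "impute_mode", "impute_rsample",
    "impute_knn", "impute_chained", "impute_rf", "impute_bagged_trees",
    "impute_em_mvnorm",
]

N_REPEATS_DEFAULT = 20   # replicate count of the _repeated variants
N_TREES_DEFAULT = 25     # trees per forest / forest-like ensemble
N_BAGS_DEFAULT = 25      # trees in the bagged-trees imputer
PMM_DONORS = 5
CHAINED_CYCLES = 5


class ImputationFailure(RuntimeError):
    """Raised inside a method when imputation cannot proceed; captured by
    :func:`run_method` ('missing values are retained as NA')."""


@dataclass
class MethodSpec:
    """A registered imputer: name, category, stochasticity and repeat count."""

    name: str
    category: str            # univariate | multivariate | poisoned | calibrating
    stochastic: bool = False
    n_repeats: int = 1
    params: dict = field(default_factory=dict)


@dataclass
class ImputationOutcome:
    table: NumericTable
    failed: bool = False
    failure_message: str = ""


def _missing_mask(table: NumericTable) -> np.ndarray:
    return np.isnan(table.values)


# ---------------------------------------------------------------------------
# univariate methods

def _fill_columnwise(table: NumericTable, fill_fn) -> ImputationOutcome:
    out = table.copy()
    miss = _missing_mask(table)
    for j in range(table.n_cols):
        rows = np.flatnonzero(miss[:, j])
        if rows.size == 0:
            continue
        obs = table.observed_column(j)
        if obs.size == 0:
            raise ImputationFailure(f"column {table.col_ids[j]} has no observed values")
        out.values[rows, j] = fill_fn(obs, rows)
    return ImputationOutcome(out)


def impute_mean(table: NumericTable) -> ImputationOutcome:
    return _fill_columnwise(table, lambda obs, rows: float(np.mean(obs)))


def impute_median(table: NumericTable) -> ImputationOutcome:
    return _fill_columnwise(table, lambda obs, rows: float(np.median(obs)))


def half_sample_mode(values: np.ndarray) -> float:
    """Robust mode of continuous data: recursively keep the half sample with
    the smallest range, return the mean of the final <=2 values."""
    v = np.sort(np.asarray(values, dtype=float))
    while v.size > 2:
        h = (v.size + 1) // 2
        widths = v[h - 1:] - v[: v.size - h + 1]
        start = int(np.argmin(widths))
        v = v[start:start + h]
    return float(v.mean())


def impute_mode(table: NumericTable) -> ImputationOutcome:
    """Most frequent observed value (ties broken toward the smallest); when
    all observed values are unique, falls back to the half-sample mode."""

    def _mode(obs, rows):
        uniq, counts = np.unique(obs, return_counts=True)
        if counts.max() == 1:
            return half_sample_mode(uniq)
        return float(uniq[np.argmax(counts)])  # first max = smallest value

    return _fill_columnwise(table, _mode)


def impute_rsample(table: NumericTable, seed: int = 0) -> ImputationOutcome:
    rng = np.random.default_rng(seed)
    return _fill_columnwise(
        table, lambda obs, rows: rng.choice(obs, size=rows.size, replace=True)
    )


# ---------------------------------------------------------------------------
# k-nearest neighbours

def impute_knn(table: NumericTable, k: int) -> ImputationOutcome:
    """Distance-based fill: standardized Euclidean over pairwise-complete
    columns, divided by the shared-column count; ties broken by row order;
    ``k`` is clamped to the available donor count."""
    if k < 1:
        raise ValueError("k must be >= 1")
    X = table.values
    miss = np.isnan(X)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    out = table.copy()
    rows, cols = np.nonzero(miss)
    for i, j in zip(rows, cols):
        donors = np.flatnonzero(~miss[:, j])
        zi = Z[i]
        shared = (~np.isnan(zi)[None, :]) & (~np.isnan(Z[donors]))
        n_shared = shared.sum(axis=1)
        ok = n_shared > 0
        if not ok.any():
            raise ImputationFailure(
                f"row {i + 1} shares no observed column with any donor for "
                f"{table.col_ids[j]}"
            )
        donors, shared, n_shared = donors[ok], shared[ok], n_shared[ok]
        diff = np.where(shared, Z[donors] - zi[None, :], 0.0)
        dist = np.sqrt((diff * diff).sum(axis=1)) / n_shared
        kk = min(k, donors.size)
        order = np.argsort(dist, kind="stable")[:kk]
        out.values[i, j] = float(X[donors[order], j].mean())
    return ImputationOutcome(out)


# ---------------------------------------------------------------------------
# chained equations (linear / pmm / cart) and forests

def _ridge_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with a tiny ridge so singular designs never fail."""
    A = np.column_stack([np.ones(len(X)), X])
    G = A.T @ A
    lam = 1e-8 * max(1.0, np.trace(G) / G.shape[0])
    return np.linalg.solve(G + lam * np.eye(G.shape[0]), A.T @ y)


def _ridge_predict(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X]) @ beta


class _Forest:
    """Bagged regression trees with per-tree bootstrap (random-forest style).

    Implemented as an explicit tree loop so small-table fits stay cheap;
    keeps per-tree training targets for leaf-donor draws.
    """

    def __init__(self, n_trees: int, seed: int, max_features=None):
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features
        self.trees: list[DecisionTreeRegressor] = []
        self.boot_y: list[np.ndarray] = []
        self.leaf_of_train: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Forest":
        rng = np.random.default_rng(self.seed)
        n = len(y)
        for t in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            tree = DecisionTreeRegressor(
                max_features=self.max_features,
                min_samples_leaf=5,   # regression-forest terminal node size
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X[idx], y[idx])
            self.trees.append(tree)
            self.boot_y.append(y[idx])
            self.leaf_of_train.append(tree.apply(X[idx]))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        acc = np.zeros(len(X))
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / self.n_trees

    def draw_leaf_donor(self, x_row: np.ndarray, rng: np.random.Generator) -> float:
        t = int(rng.integers(0, self.n_trees))
        leaf = self.trees[t].apply(x_row.reshape(1, -1))[0]
        donors = self.boot_y[t][self.leaf_of_train[t] == leaf]
        return float(rng.choice(donors))


def _median_initialize(table: NumericTable) -> np.ndarray:
    X = table.values.copy()
    miss = np.isnan(X)
    for j in range(X.shape[1]):
        obs = X[~miss[:, j], j]
        if obs.size == 0:
            raise ImputationFailure(f"column {table.col_ids[j]} has no observed values")
        X[miss[:, j], j] = np.median(obs)
    return X


def impute_chained(
    table: NumericTable,
    model: str = "linear",
    seed: int = 0,
    n_cycles: int = CHAINED_CYCLES,
    n_trees: int = N_TREES_DEFAULT,
) -> ImputationOutcome:
    """Chained-equations imputation.

    Missing cells are median-initialized; for ``n_cycles`` the columns with
    missingness are visited left to right, each regressed on all others with
    the currently filled values and refilled — ``linear``: prediction plus
    Gaussian noise at the residual sd; ``pmm``: draw among the 5 observed
    donors with closest fitted values; ``cart``: draw from the donor leaf of
    a regression tree; ``rf``: draw from a random forest tree's donor leaf.
    """
    if model not in ("linear", "pmm", "cart", "rf"):
        raise ValueError(f"unknown chained model {model!r}")
    miss = _missing_mask(table)
    X = _median_initialize(table)
    rng = np.random.default_rng(child_seed(seed, "chained", model))
    targets = [j for j in range(table.n_cols) if miss[:, j].any()]
    if model == "pmm":
        for j in targets:
            if (~miss[:, j]).sum() < PMM_DONORS:
                raise ImputationFailure(
                    f"column {table.col_ids[j]} has fewer than {PMM_DONORS} donors"
                )
    for _cycle in range(n_cycles):
        for j in targets:
            obs = ~miss[:, j]
            pred_cols = [c for c in range(table.n_cols) if c != j]
            Xo, yo = X[np.ix_(obs, pred_cols)], X[obs, j]
            Xm = X[np.ix_(miss[:, j], pred_cols)]
            if model == "linear":
                beta = _ridge_fit(Xo, yo)
                resid = yo - _ridge_predict(beta, Xo)
                sd = float(np.std(resid, ddof=min(len(resid) - 1, len(pred_cols) + 1)))
                X[miss[:, j], j] = _ridge_predict(beta, Xm) + rng.normal(0, sd, size=len(Xm))
            elif model == "pmm":
                beta = _ridge_fit(Xo, yo)
                fit_o = _ridge_predict(beta, Xo)
                fit_m = _ridge_predict(beta, Xm)
                fills = np.empty(len(Xm))
                for r, fm in enumerate(fit_m):
                    order = np.argsort(np.abs(fit_o - fm), kind="stable")[:PMM_DONORS]
                    fills[r] = yo[order[rng.integers(0, len(order))]]
                X[miss[:, j], j] = fills
            elif model == "cart":
                tree = DecisionTreeRegressor(
                    min_samples_leaf=5, random_state=int(rng.integers(0, 2**31 - 1))
                ).fit(Xo, yo)
                leaves_o = tree.apply(Xo)
                leaves_m = tree.apply(Xm)
                fills = np.empty(len(Xm))
                for r, leaf in enumerate(leaves_m):
                    donors = yo[leaves_o == leaf]
                    fills[r] = donors[rng.integers(0, len(donors))]
                X[miss[:, j], j] = fills
            else:  # rf
                forest = _Forest(n_trees, int(rng.integers(0, 2**31 - 1)),
                                 max_features=1 / 3).fit(Xo, yo)
                X[miss[:, j], j] = [forest.draw_leaf_donor(x, rng) for x in Xm]
    out = table.copy()
    out.values[miss] = X[miss]
    return ImputationOutcome(out)


def impute_rf(
    table: NumericTable,
    variant: str = "iterative",
    seed: int = 0,
    n_trees: int = N_TREES_DEFAULT,
) -> ImputationOutcome:
    """Random-forest imputation.

    ``iterative`` mirrors the missForest scheme: median-initialize, then
    repeat column-wise forest refits (columns visited by ascending
    missingness) until the summed squared change in the imputed values first
    increases, or 10 sweeps; the previous sweep's values are returned.
    ``chained`` places a forest inside the chained-equations loop with
    leaf-donor draws.
    """
    if variant == "chained":
        return impute_chained(table, model="rf", seed=seed, n_trees=n_trees)
    if variant != "iterative":
        raise ValueError(f"unknown rf variant {variant!r}")
    miss = _missing_mask(table)
    if not miss.any():
        return ImputationOutcome(table.copy())
    X = _median_initialize(table)
    rng = np.random.default_rng(child_seed(seed, "rf_iterative"))
    targets = sorted(
        (j for j in range(table.n_cols) if miss[:, j].any()),
        key=lambda j: miss[:, j].sum(),
    )
    prev_change = np.inf
    best = X.copy()
    for _sweep in range(10):
        X_new = X.copy()
        for j in targets:
            obs = ~miss[:, j]
            pred_cols = [c for c in range(table.n_cols) if c != j]
            col_obs = X_new[np.ix_(obs, pred_cols)]
            col_y = X_new[obs, j]
            if np.all(col_y == col_y[0]):
                X_new[miss[:, j], j] = col_y[0]  # constant column fallback
                continue
            forest = _Forest(n_trees, int(rng.integers(0, 2**31 - 1)),
                             max_features=1 / 3).fit(col_obs, col_y)
            X_new[miss[:, j], j] = forest.predict(X_new[np.ix_(miss[:, j], pred_cols)])
        change = float(((X_new[miss] - X[miss]) ** 2).sum())
        if change >= prev_change:
            break  # first increase: keep previous sweep's values
        best = X_new.copy()
        prev_change = change
        X = X_new
    out = table.copy()
    out.values[miss] = best[miss]
    return ImputationOutcome(out)


def impute_bagged_trees(
    table: NumericTable, n_bags: int = N_BAGS_DEFAULT, seed: int = 0
) -> ImputationOutcome:
    """Per target column, average the predictions of ``n_bags`` regression
    trees fit on bootstrap resamples of the rows observed for that column."""
    miss = _missing_mask(table)
    if not miss.any():
        return ImputationOutcome(table.copy())
    X = _median_initialize(table)
    rng = np.random.default_rng(child_seed(seed, "bag"))
    out = table.copy()
    for j in range(table.n_cols):
        if not miss[:, j].any():
            continue
        obs = ~miss[:, j]
        if obs.sum() == 0:
            raise ImputationFailure(f"no donor rows for column {table.col_ids[j]}")
        pred_cols = [c for c in range(table.n_cols) if c != j]
        forest = _Forest(n_bags, int(rng.integers(0, 2**31 - 1))).fit(
            X[np.ix_(obs, pred_cols)], X[obs, j]
        )
        out.values[miss[:, j], j] = forest.predict(X[np.ix_(miss[:, j], pred_cols)])
    return ImputationOutcome(out)


# ---------------------------------------------------------------------------
# EM multivariate-normal multiple imputation

_EM_CACHE: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}


def em_mvnorm_fit(
    values: np.ndarray, max_iter: int = 500, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """EM estimate of the MVN mean/covariance (ML, denominator n) from
    incomplete data.  Rows are processed grouped by missing-data pattern;
    raises :class:`ImputationFailure` on non-convergence.  The fit is
    deterministic, so results are memoized per input matrix (repeated
    multiple-imputation draws reuse one fit)."""
    X = np.asarray(values, dtype=float)
    key = X.tobytes()
    if key in _EM_CACHE:
        mu, sigma = _EM_CACHE[key]
        return mu.copy(), sigma.copy()
    n, p = X.shape
    miss = np.isnan(X)
    patterns, inverse = np.unique(miss, axis=0, return_inverse=True)
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[var == 0] = 1e-8
    sigma = np.diag(var)
    for _it in range(max_iter):
        S = np.zeros((p, p))
        Xhat = X.copy()
        for pi, pat in enumerate(patterns):
            idx = np.flatnonzero(inverse == pi)
            if not pat.any():
                continue
            o, m = ~pat, pat
            soo = sigma[np.ix_(o, o)]
            smo = sigma[np.ix_(m, o)]
            K = np.linalg.solve(soo, smo.T)          # (|o|, |m|)
            Xhat[np.ix_(idx, m)] = mu[m] + (X[np.ix_(idx, o)] - mu[o]) @ K
            C = sigma[np.ix_(m, m)] - smo @ K
            S[np.ix_(m, m)] += len(idx) * C
        S += Xhat.T @ Xhat
        mu_new = Xhat.mean(axis=0)
        sigma_new = S / n - np.outer(mu_new, mu_new)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            if len(_EM_CACHE) > 32:
                _EM_CACHE.clear()
            _EM_CACHE[key] = (mu.copy(), sigma.copy())
            return mu, sigma
    raise ImputationFailure(f"EM did not converge in {max_iter} iterations")


def impute_em_mvnorm(table: NumericTable, seed: int = 0, max_iter: int = 500) -> ImputationOutcome:
    """EM-based multivariate-normal imputation: fit (mu, Sigma) by EM, then
    fill each incomplete row with a draw (not the conditional mean) from the
    conditional normal given the row's observed cells."""
    if table.n_rows <= table.n_cols:
        raise ImputationFailure("EM needs more rows than columns")
    miss = _missing_mask(table)
    if not miss.any():
        return ImputationOutcome(table.copy())
    mu, sigma = em_mvnorm_fit(table.values)
    rng = np.random.default_rng(child_seed(seed, "em"))
    out = table.copy()
    for i in range(table.n_rows):
        m = miss[i]
        if not m.any():
            continue
        o = ~m
        if not o.any():
            raise ImputationFailure(f"row {i + 1} has no observed cells")
        soo = sigma[np.ix_(o, o)]
        smo = sigma[np.ix_(m, o)]
        cond_mu = mu[m] + smo @ np.linalg.solve(soo, table.values[i, o] - mu[o])
        cond_cov = sigma[np.ix_(m, m)] - smo @ np.linalg.solve(soo, smo.T)
        # symmetrize + jitter-free PSD square root via eigen decomposition
        cond_cov = (cond_cov + cond_cov.T) / 2.0
        evals, evecs = np.linalg.eigh(cond_cov)
        root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
        out.values[i, m] = cond_mu + root @ rng.standard_normal(m.sum())
    return ImputationOutcome(out)


# ---------------------------------------------------------------------------
# registry and dispatch

def _impl(name: str, params: dict, table: NumericTable, seed: int, truth):
    if name == "mean":
        return impute_mean(table)
    if name == "median":
        return impute_median(table)
    if name == "mode":
        return impute_mode(table)
    if name == "rSample":
        return impute_rsample(table, seed)
    if name.startswith("knn"):
        return impute_knn(table, k=params["k"])
    if name == "linear":
        return impute_chained(table, model="linear", seed=seed)
    if name.startswith("pmm"):
        return impute_chained(table, model="pmm", seed=seed)
    if name.startswith("cart"):
        return impute_chained(table, model="cart", seed=seed)
    if name.startswith("bag"):
        return impute_bagged_trees(table, seed=seed)
    if name.startswith("rf_chained"):
        return impute_rf(table, variant="chained", seed=seed, n_trees=params["n_trees"])
    if name.startswith("rf_iterative"):
        return impute_rf(table, variant="iterative", seed=seed, n_trees=params["n_trees"])
    if name.startswith("em_mvnorm"):
        return impute_em_mvnorm(table, seed=seed)
    if name in ("plus", "factor", "plusminus"):
        if truth is None:
            raise ValueError(f"reference method {name!r} needs the truth map")
        return ImputationOutcome(fill_reference(table, truth, name, params["c"], seed))
    if name.startswith("tinyNoise_"):
        if truth is None:
            raise ValueError(f"reference method {name!r} needs the truth map")
        return ImputationOutcome(fill_reference(table, truth, "tinynoise", params["c"], seed))
    raise KeyError(f"unknown method {name!r}")


def _fmt_c(c: float) -> str:
    return np.format_float_positional(c, trim="-")


def default_registry(
    n_trees: int = N_TREES_DEFAULT, n_repeats: int = N_REPEATS_DEFAULT
) -> dict[str, MethodSpec]:
    """The full method roster: 4 univariate, 18 multivariate, 3 poisoned and
    10 calibrating methods (M = 35)."""
    specs: list[MethodSpec] = [
        MethodSpec("mean", "univariate"),
        MethodSpec("median", "univariate"),
        MethodSpec("mode", "univariate"),
        MethodSpec("rSample", "univariate", stochastic=True),
        MethodSpec("linear", "multivariate", stochastic=True),
    ]
    for k in (3, 5, 7, 9, 10):
        specs.append(MethodSpec(f"knn{k}", "multivariate", params={"k": k}))
    for base in ("pmm", "cart", "bag", "rf_chained", "rf_iterative", "em_mvnorm"):
        params = {"n_trees": n_trees} if base.startswith("rf") else {}
        specs.append(MethodSpec(base, "multivariate", stochastic=True, params=dict(params)))
        specs.append(
            MethodSpec(
                f"{base}_repeated", "multivariate", stochastic=True,
                n_repeats=n_repeats, params=dict(params),
            )
        )
    for name in ("plus", "factor", "plusminus"):
        specs.append(
            MethodSpec(name, "poisoned", stochastic=False, params={"c": DEFAULT_C[name]})
        )
    for c in TINYNOISE_GRID:
        specs.append(
            MethodSpec(
                f"tinyNoise_{_fmt_c(c)}", "calibrating", stochastic=True, params={"c": c}
            )
        )
    return {s.name: s for s in specs}


def run_method(
    spec: MethodSpec, table: NumericTable, seed: int, truth=None
) -> ImputationOutcome:
    """Dispatch a registered method; average ``n_repeats`` seeded replicates
    cell-wise; capture any internal exception as a failed outcome."""
    miss = _missing_mask(table)
    try:
        if spec.n_repeats <= 1:
            return _impl(spec.name, spec.params, table, seed, truth)
        acc = np.zeros(int(miss.sum()))
        for rep in range(spec.n_repeats):
            rep_seed = child_seed(seed, spec.name, "rep", rep)
            outcome = _impl(spec.name, spec.params, table, rep_seed, truth)
            if outcome.failed:
                return outcome
            acc += outcome.table.values[miss]
        out = table.copy()
        out.values[miss] = acc / spec.n_repeats
        return ImputationOutcome(out)
    except KeyError:
        raise
    except Exception as exc:  # failure capture contract
        return ImputationOutcome(table.copy(), failed=True, failure_message=str(exc))
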