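"""Orchestration of the full method comparison.

The benchmark inserts diagnostic missing values (k iterations), runs every
registered method on each masked table, scores the imputations per variable
with the gated robust metrics and zDelta, ranks methods per (variable,
iteration, metric), aggregates to the mean rank R_m, standardizes via the
Irwin–Hall/Gaussian approximation, categorizes with computed ABC, picks the
winner among genuine methods, and contrasts the best univariate with the
best multivariate method.  Optionally the winner is applied to the
persistent (real) missing cells.

All randomness flows through seeds derived by stable hashing from the run
seed, method name and iteration, so results are identical for any number
of worker processes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .imputers import MethodSpec, default_registry, run_method, N_TREES_DEFAULT
from .metrics import GATE_ALPHA, PairedValues, evaluate_pairs
from .missingness import MaskPlan, apply_mask, build_mask_plan
from .seeding import child_seed
from .selection import (
    RankCube, SelectionResult, abc_score, aggregate_ranks, cabc_categorize,
    compare_uni_multi, rank_slice, select_best, standardize_rank,
)
from .tabular import CellRef, NumericTable, missing_cells

__all__ = [
    "RunConfig", "RunReport", "compare_imputation_methods", "impute_data",
    "persistent_selection",
]


@dataclass
class RunConfig:
    """User-facing parameters of a comparison run."""

    p_miss: float = 0.1                 # diagnostic masking proportion
    p_persistent: float = 0.0           # persistent masking proportion (complete inputs)
    k_iterations: int = 10
    seed: int = 0
    mechanism: str = "MCAR"
    mnar_shape: float = 1.0
    methods: list[str] | None = None    # genuine-method subset; references always added
    gate_alpha: float = GATE_ALPHA
    n_cores: int = 1
    produce_final_imputations: bool = False
    n_trees: int = N_TREES_DEFAULT
    n_repeats_stochastic: int = 20
    corrected_variance: bool = False
    n_permutations: int = 2000

    def validate(self) -> None:
        if not (0.0 < self.p_miss < 1.0):
            raise ValueError("p_miss must be in (0, 1)")
        if not (0.0 <= self.p_persistent < 1.0):
            raise ValueError("p_persistent must be in [0, 1)")
        if self.k_iterations < 1:
            raise ValueError("k_iterations must be >= 1")
        if self.mechanism not in ("MCAR", "MNAR"):
            raise ValueError("mechanism must be MCAR or MNAR")
        if self.n_cores < 1:
            raise ValueError("n_cores must be >= 1")

    def registry(self) -> dict[str, MethodSpec]:
        reg = default_registry(
            n_trees=self.n_trees, n_repeats=self.n_repeats_stochastic
        )
        if self.methods is None:
            return reg
        unknown = [m for m in self.methods if m not in reg]
        if unknown:
            raise ValueError(f"unknown method(s): {', '.join(unknown)}")
        keep = set(self.methods)
        return {
            name: spec for name, spec in reg.items()
            if name in keep or spec.category in ("poisoned", "calibrating")
        }


@dataclass
class RunReport:
    selection: SelectionResult
    long_results: pd.DataFrame
    zdelta_summary: dict
    config: RunConfig
    mask_plan_digest: str
    failures: dict[str, list[int]]
    uni_multi: dict
    method_category: dict[str, str]
    final_table: NumericTable | None = None
    notice: str = ""

    def to_json(self) -> str:
        sel = self.selection
        payload = {
            "schema": 1,
            "config": asdict(self.config),
            "notice": self.notice,
            "mask_plan_digest": self.mask_plan_digest,
            "M": sel.M,
            "d": sel.d,
            "mean_rank": sel.R,
            "Z": sel.Z,
            "p": sel.p,
            "abc_score": sel.abc_score,
            "category": sel.category,
            "method_category": self.method_category,
            "best_method": sel.best_method,
            "warnings": sel.warnings,
            "failures": self.failures,
            "uni_multi": self.uni_multi,
            "zdelta_mean": self.zdelta_summary.get("per_method", {}),
            "zdelta_per_variable": self.zdelta_summary.get("per_method_variable", {}),
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=float)

    def rankings_frame(self) -> pd.DataFrame:
        sel = self.selection
        rows = [
            {
                "method": m,
                "category": self.method_category.get(m, ""),
                "mean_rank": sel.R[m],
                "Z": sel.Z[m],
                "p": sel.p[m],
                "abc_score": sel.abc_score.get(m, np.nan),
                "abc_category": sel.category.get(m, ""),
                "zdelta_mean": self.zdelta_summary["per_method"].get(m, np.nan),
            }
            for m in sorted(sel.R, key=lambda mm: sel.R[mm])
        ]
        return pd.DataFrame(rows)

    def categories_frame(self) -> pd.DataFrame:
        sel = self.selection
        rows = [
            {"method": m, "abc_category": c, "abc_score": sel.abc_score.get(m, np.nan)}
            for m, c in sorted(sel.category.items(), key=lambda kv: (kv[1], kv[0]))
        ]
        return pd.DataFrame(rows)


def _column_stats(table: NumericTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean/sd for zDelta from the complete (pre-masking) data;
    observed cells substitute when the input itself is incomplete."""
    mu = np.nanmean(table.values, axis=0)
    sd = np.nanstd(table.values, axis=0, ddof=1)
    if (sd == 0).any() or np.isnan(sd).any():
        raise ValueError("constant column: zDelta undefined")
    return mu, sd


def _job(spec: MethodSpec, masked: NumericTable, truth_j: dict, iteration: int,
         seed: int, col_mu, col_sd, col_ids, alpha: float) -> dict:
    """Impute one (method, iteration) and score it per variable."""
    needs_truth = spec.category in ("poisoned", "calibrating")
    outcome = run_method(spec, masked, seed, truth=truth_j if needs_truth else None)
    result = {
        "method": spec.name, "iteration": iteration,
        "failed": outcome.failed, "message": outcome.failure_message,
        "records": [],
    }
    if outcome.failed:
        return result
    by_col: dict[int, list[CellRef]] = {}
    for cell in truth_j:
        by_col.setdefault(cell.col_index, []).append(cell)
    for j in sorted(by_col):
        cells = sorted(by_col[j], key=lambda c: c.row_index)
        truth_vals = np.array([truth_j[c] for c in cells])
        imput_vals = np.array(
            [outcome.table.values[c.row_index, c.col_index] for c in cells]
        )
        if np.isnan(imput_vals).any():
            # cells the method left unfilled: treat the iteration as failed
            result["failed"] = True
            result["message"] = f"unfilled diagnostic cells in {col_ids[j]}"
            result["records"] = []
            return result
        pairs = PairedValues(truth_vals, imput_vals, variable=col_ids[j],
                             iteration=iteration)
        rec = evaluate_pairs(pairs, col_mu[j], col_sd[j], alpha)
        result["records"].append({
            "variable": col_ids[j], "col_index": j, "n": len(cells),
            "rmsd": rec.rmsd, "md": rec.md, "rbias": rec.rbias,
            "p_rmsd": rec.p_rmsd, "p_md": rec.p_md, "p_rbias": rec.p_rbias,
            "gated_rmsd": rec.gated_rmsd, "gated_md": rec.gated_md,
            "gated_rbias": rec.gated_rbias, "zdelta": rec.zdelta,
        })
    return result


def _evaluate_all(
    registry: dict[str, MethodSpec],
    masked_tables: list[NumericTable],
    truths: list[dict],
    config: RunConfig,
    col_mu, col_sd, col_ids,
) -> list[dict]:
    jobs = [
        (spec, masked_tables[j], truths[j], j,
         child_seed(config.seed, name, "iter", j))
        for name, spec in sorted(registry.items())
        for j in range(len(masked_tables))
    ]
    if config.n_cores > 1:
        results = Parallel(n_jobs=config.n_cores)(
            delayed(_job)(spec, masked, truth, j, seed, col_mu, col_sd, col_ids,
                          config.gate_alpha)
            for spec, masked, truth, j, seed in jobs
        )
    else:
        results = [
            _job(spec, masked, truth, j, seed, col_mu, col_sd, col_ids,
                 config.gate_alpha)
            for spec, masked, truth, j, seed in jobs
        ]
    return list(results)


def _build_selection(
    results: list[dict],
    registry: dict[str, MethodSpec],
    col_ids: list[str],
    k: int,
    config: RunConfig,
) -> tuple[SelectionResult, pd.DataFrame, dict, dict[str, list[int]]]:
    methods = sorted(registry)
    m_index = {m: i for i, m in enumerate(methods)}
    M, V = len(methods), len(col_ids)
    failed = np.zeros((M, k), dtype=bool)
    gated = np.full((M, V, k, 3), np.nan)
    raw_rmsd = np.full((M, V, k), np.nan)
    zdelta_vals = np.full((M, V, k), np.nan)
    n_cells = np.zeros((M, V, k))
    long_rows = []
    messages: dict[str, list[int]] = {}
    for res in results:
        mi, it = m_index[res["method"]], res["iteration"]
        if res["failed"]:
            failed[mi, it] = True
            messages.setdefault(res["method"], []).append(it)
            continue
        for rec in res["records"]:
            vi = rec["col_index"]
            gated[mi, vi, it, :] = (rec["gated_rmsd"], rec["gated_md"], rec["gated_rbias"])
            raw_rmsd[mi, vi, it] = rec["rmsd"]
            zdelta_vals[mi, vi, it] = rec["zdelta"]
            n_cells[mi, vi, it] = rec["n"]
            for metric, raw, gat, p in (
                ("RMSD", rec["rmsd"], rec["gated_rmsd"], rec["p_rmsd"]),
                ("MD", rec["md"], rec["gated_md"], rec["p_md"]),
                ("rBias", rec["rbias"], rec["gated_rbias"], rec["p_rbias"]),
                ("zDelta", rec["zdelta"], rec["zdelta"], np.nan),
            ):
                long_rows.append(
                    (res["method"], rec["variable"], it, metric, raw, gat, p)
                )
    if failed.all(axis=1).all():
        raise RuntimeError(f"every method failed on every iteration: {messages}")

    # rank cube: per (variable, iteration, metric) slice across methods
    ranks = np.full((M, V, k, 3), np.nan)
    for vi in range(V):
        for it in range(k):
            if np.isnan(gated[:, vi, it, 0][~failed[:, it]]).all():
                continue  # slice without diagnostic cells
            for met in range(3):
                vals = gated[:, vi, it, met]
                ranks[:, vi, it, met] = rank_slice(vals, failed[:, it])
    cube = RankCube(methods, ranks)
    R = aggregate_ranks(cube)
    d = cube.d_effective
    Z, P = {}, {}
    for m in methods:
        Z[m], P[m] = standardize_rank(R[m], M, d, corrected=config.corrected_variance)
    method_category = {m: registry[m].category for m in methods}
    scores = {
        m: abc_score(Z[m]) for m in methods if method_category[m] != "calibrating"
    }
    category, cabc_warnings = cabc_categorize(scores)
    with np.errstate(invalid="ignore"):
        mean_rmsd = {
            m: float(np.nanmean(raw_rmsd[m_index[m]]))
            if not np.isnan(raw_rmsd[m_index[m]]).all() else float("inf")
            for m in methods
        }
    best, warn = select_best(R, category, method_category, mean_rmsd)
    warnings = cabc_warnings + warn

    # zDelta summaries (cell-weighted means)
    per_method, per_method_variable = {}, {}
    for m in methods:
        zi, ni = zdelta_vals[m_index[m]], n_cells[m_index[m]]
        ok = ~np.isnan(zi)
        per_method[m] = float((zi[ok] * ni[ok]).sum() / ni[ok].sum()) if ok.any() else float("nan")
        per_var = {}
        for vi, v in enumerate(col_ids):
            okv = ok[vi]
            if okv.any():
                per_var[v] = float((zi[vi][okv] * ni[vi][okv]).sum() / ni[vi][okv].sum())
        per_method_variable[m] = per_var
    zsummary = {
        "per_method": per_method,
        "per_method_variable": per_method_variable,
        "pools": {
            m: [float(x) for x in zdelta_vals[m_index[m]][~np.isnan(zdelta_vals[m_index[m]])]]
            for m in methods
        },
    }
    sel = SelectionResult(
        R=R, Z=Z, p=P, abc_score=scores, category=category,
        best_method=best, warnings=warnings, M=M, d=d,
    )
    long_df = pd.DataFrame(
        long_rows,
        columns=["method", "variable", "iteration", "metric", "raw", "gated", "p_gate"],
    )
    return sel, long_df, zsummary, messages


def _uni_multi_comparison(
    sel: SelectionResult, zsummary: dict, method_category: dict, config: RunConfig
) -> dict:
    genuine = {m: sel.R[m] for m in sel.R if method_category[m] in ("univariate", "multivariate")}
    unis = {m: r for m, r in genuine.items() if method_category[m] == "univariate"}
    multis = {m: r for m, r in genuine.items() if method_category[m] == "multivariate"}
    out = {"best_univariate": None, "best_multivariate": None,
           "p_dts": None, "p_wilcoxon": None, "p_fisher": None}
    if not unis or not multis:
        return out
    bu = min(unis, key=lambda m: (unis[m], m))
    bm = min(multis, key=lambda m: (multis[m], m))
    out["best_univariate"], out["best_multivariate"] = bu, bm
    pool_u = zsummary["pools"].get(bu, [])
    pool_m = zsummary["pools"].get(bm, [])
    if len(pool_u) >= 5 and len(pool_m) >= 5:
        p_dts, p_w, p_f = compare_uni_multi(
            pool_u, pool_m, n_permutations=config.n_permutations,
            seed=child_seed(config.seed, "uni_multi"),
        )
        out.update({"p_dts": p_dts, "p_wilcoxon": p_w, "p_fisher": p_f})
    return out


def compare_imputation_methods(table: NumericTable, config: RunConfig) -> RunReport:
    """Run the complete comparison (masking, imputation, metrics, ranking,
    cABC categorization, winner selection) on a numeric table."""
    config.validate()
    table.validate()
    registry = config.registry()
    real_missing = missing_cells(table)
    if (not real_missing and config.produce_final_imputations
            and config.p_persistent == 0.0):
        sel = SelectionResult({}, {}, {}, {}, {}, best_method="", M=0, d=0)
        return RunReport(
            selection=sel, long_results=pd.DataFrame(), zdelta_summary={"per_method": {}},
            config=config, mask_plan_digest="", failures={}, uni_multi={},
            method_category={}, final_table=table.copy(),
            notice="no missing values detected; returning the original dataset",
        )
    plan = build_mask_plan(
        table, p_miss=config.p_miss, k=config.k_iterations,
        mechanism=config.mechanism, shape=config.mnar_shape,
        seed=config.seed, p_persistent=config.p_persistent,
    )
    col_mu, col_sd = _column_stats(table)
    base_masked = table.copy()
    for c in plan.persistent:
        base_masked.values[c.row_index, c.col_index] = np.nan
    masked_tables, truths = [], []
    for cells in plan.diagnostic:
        masked, truth = apply_mask(base_masked, cells)
        masked_tables.append(masked)
        truths.append(truth)
    results = _evaluate_all(
        registry, masked_tables, truths, config, col_mu, col_sd, table.col_ids
    )
    sel, long_df, zsummary, failures = _build_selection(
        results, registry, table.col_ids, plan.k, config
    )
    method_category = {m: registry[m].category for m in registry}
    uni_multi = _uni_multi_comparison(sel, zsummary, method_category, config)
    digest = hashlib.sha256(plan.to_json().encode()).hexdigest()
    final = None
    if config.produce_final_imputations and missing_cells(base_masked):
        outcome = run_method(
            registry[sel.best_method], base_masked,
            child_seed(config.seed, "final", sel.best_method),
        )
        if outcome.failed:
            raise RuntimeError(
                f"selected method {sel.best_method!r} failed on the real "
                f"missing cells: {outcome.failure_message}"
            )
        final = outcome.table
    return RunReport(
        selection=sel, long_results=long_df, zdelta_summary=zsummary,
        config=config, mask_plan_digest=digest, failures=failures,
        uni_multi=uni_multi, method_category=method_category, final_table=final,
    )


def persistent_selection(table: NumericTable, plan: MaskPlan, config: RunConfig) -> SelectionResult:
    """Re-run scoring and categorization with the persistent cells as the
    single evaluation set (requires their truth, i.e. a generated plan).

    This is the generalization check: the diagnostic winner should land in
    the persistent evaluation's cABC A subset.
    """
    if not plan.persistent:
        raise ValueError("plan has no persistent cells")
    truth = {c: plan.truth[c] for c in plan.persistent if c in plan.truth}
    if len(truth) != len(plan.persistent):
        raise ValueError("persistent truth unknown (table had real missing cells)")
    registry = config.registry()
    col_mu, col_sd = _column_stats(table)
    masked, _ = apply_mask(table, plan.persistent)
    results = _evaluate_all(
        registry, [masked], [truth], config, col_mu, col_sd, table.col_ids
    )
    sel, _, _, _ = _build_selection(results, registry, table.col_ids, 1, config)
    return sel


def impute_data(table: NumericTable, method: str = "AUTO",
                config: RunConfig | None = None) -> NumericTable:
    """Fill a table's real missing cells with an explicit method or with the
    winner of a diagnostic comparison (``method='AUTO'``)."""
    config = config or RunConfig()
    cells = missing_cells(table)
    if not cells:
        raise ValueError("nothing to impute: table has no missing cells")
    if method == "AUTO":
        cfg = RunConfig(**{**asdict(config), "produce_final_imputations": True})
        report = compare_imputation_methods(table, cfg)
        assert report.final_table is not None
        return report.final_table
    registry = config.registry()
    if method not in registry:
        raise ValueError(f"unknown method {method!r}")
    outcome = run_method(
        registry[method], table, child_seed(config.seed, "impute", method)
    )
    if outcome.failed:
        raise RuntimeError(f"method {method!r} failed: {outcome.failure_message}")
    return outcome.table
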