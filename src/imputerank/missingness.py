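"""Persistent and diagnostic artificial missingness under MCAR or MNAR.

Persistent cells are removed once and stay missing (the stand-in for a
dataset's real missing values); diagnostic cells are removed per iteration
and restored afterwards, so each imputer's output can be compared with the
known truth.  Masking is per-cell Bernoulli with probability ``p_miss``;
under MNAR the per-cell probability is tilted by the cell's within-column
quantile through an exponential weight ``w(q; s) = exp(s * q)`` normalised
to keep the expected masked fraction at ``p_miss`` (``s = 0`` recovers MCAR).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tabular import CellRef, NumericTable, missing_cells
from .seeding import child_seed

__all__ = ["MaskPlan", "make_persistent_mask", "make_diagnostic_masks", "apply_mask"]

MAX_RETRIES = 100


@dataclass
class MaskPlan:
    """A persistent cell set plus per-iteration diagnostic sets with truth."""

    persistent: set[CellRef]
    diagnostic: list[set[CellRef]]
    truth: dict[CellRef, float]
    p_miss: float
    mechanism: str
    seed: int
    p_persistent: float = 0.0
    warnings: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.diagnostic)

    def validate(self) -> None:
        for j, cells in enumerate(self.diagnostic):
            if cells & self.persistent:
                raise ValueError(f"diagnostic iteration {j} overlaps the persistent set")

    def to_json(self) -> str:
        payload = {
            "p_miss": self.p_miss,
            "p_persistent": self.p_persistent,
            "mechanism": self.mechanism,
            "seed": self.seed,
            "persistent": sorted([list(c) for c in self.persistent]),
            "diagnostic": [sorted([list(c) for c in cells]) for cells in self.diagnostic],
            "truth": {f"{c.row_index},{c.col_index}": v for c, v in sorted(self.truth.items())},
        }
        return json.dumps(payload, indent=1)


def _cell_probabilities(
    table: NumericTable,
    eligible: np.ndarray,
    p_miss: float,
    mechanism: str,
    shape: float,
) -> np.ndarray:
    """Per-cell masking probabilities over the eligible boolean mask."""
    probs = np.zeros(table.values.shape, dtype=float)
    if mechanism == "MCAR" or shape == 0.0:
        probs[eligible] = p_miss
        return probs
    if mechanism != "MNAR":
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    for j in range(table.n_cols):
        col_mask = eligible[:, j]
        vals = table.values[col_mask, j]
        if vals.size == 0:
            continue
        # within-column quantile of each eligible cell, mid-ranked
        order = np.argsort(np.argsort(vals, kind="stable"), kind="stable")
        q = (order + 0.5) / vals.size
        w = np.exp(shape * q)
        p = p_miss * w / w.mean()
        probs[np.flatnonzero(col_mask), j] = np.clip(p, 0.0, 1.0)
    return probs


def _row_col_ok(observed: np.ndarray) -> bool:
    """Every column keeps >= 2 observed cells and every row >= 1."""
    return bool((observed.sum(axis=0) >= 2).all() and (observed.sum(axis=1) >= 1).all())


def _draw_mask(
    table: NumericTable,
    eligible: np.ndarray,
    p_miss: float,
    mechanism: str,
    shape: float,
    seed: int,
    base_missing: np.ndarray,
    require_nonempty: bool,
) -> set[CellRef]:
    probs = _cell_probabilities(table, eligible, p_miss, mechanism, shape)
    for attempt in range(MAX_RETRIES):
        rng = np.random.default_rng(child_seed(seed, "draw", attempt))
        drawn = (rng.random(size=probs.shape) < probs) & eligible
        if require_nonempty and not drawn.any() and eligible.any() and p_miss > 0:
            # floor: metrics need at least one diagnostic cell per iteration
            flat = np.flatnonzero(eligible)
            pick = rng.choice(flat)
            drawn.flat[pick] = True
        observed = ~(base_missing | drawn)
        if _row_col_ok(observed):
            rows, cols = np.nonzero(drawn)
            return {CellRef(int(r), int(c)) for r, c in zip(rows, cols)}
    raise RuntimeError(
        f"could not draw a mask satisfying row/column safeguards in {MAX_RETRIES} retries"
    )


def make_persistent_mask(
    table: NumericTable,
    p_miss: float,
    mechanism: str = "MCAR",
    shape: float = 0.0,
    seed: int = 0,
) -> set[CellRef]:
    """Draw the fixed subset of cells removed once at the start.

    Cells already missing in ``table`` are never candidates and are kept
    as-is.  Deterministic given ``seed``.
    """
    if not (0.0 <= p_miss < 1.0):
        raise ValueError("p_miss must be in [0, 1)")
    already = np.isnan(table.values)
    if p_miss == 0.0:
        return set()
    eligible = ~already
    return _draw_mask(
        table, eligible, p_miss, mechanism, shape,
        child_seed(seed, "persistent"), already, require_nonempty=False,
    )


def make_diagnostic_masks(
    table: NumericTable,
    persistent: set[CellRef],
    p_miss: float,
    k: int,
    mechanism: str = "MCAR",
    shape: float = 0.0,
    seed: int = 0,
) -> list[set[CellRef]]:
    """Draw ``k`` independent diagnostic cell sets from cells observed after
    persistent masking.  Each set is nonempty and disjoint from ``persistent``;
    sets may overlap across iterations."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 < p_miss < 1.0):
        raise ValueError("p_miss must be in (0, 1)")
    base_missing = np.isnan(table.values)
    for c in persistent:
        base_missing[c.row_index, c.col_index] = True
    eligible = ~base_missing
    if not eligible.any():
        raise ValueError("no eligible cells for diagnostic masking")
    masks = []
    for j in range(k):
        masks.append(
            _draw_mask(
                table, eligible, p_miss, mechanism, shape,
                child_seed(seed, "diagnostic", j), base_missing, require_nonempty=True,
            )
        )
    return masks


def apply_mask(table: NumericTable, cells: set[CellRef]) -> tuple[NumericTable, dict[CellRef, float]]:
    """Mask ``cells`` (which must all be observed); return masked table + truth map."""
    out = table.copy()
    truth: dict[CellRef, float] = {}
    for c in sorted(cells):
        v = out.values[c.row_index, c.col_index]
        if np.isnan(v):
            raise ValueError(f"cell {c} is already missing")
        truth[c] = float(v)
        out.values[c.row_index, c.col_index] = np.nan
    return out, truth


def restore(table: NumericTable, truth: dict[CellRef, float]) -> NumericTable:
    """Inverse of :func:`apply_mask`: write the saved truth back."""
    out = table.copy()
    for c, v in truth.items():
        out.values[c.row_index, c.col_index] = v
    return out


def build_mask_plan(
    table: NumericTable,
    p_miss: float,
    k: int,
    mechanism: str = "MCAR",
    shape: float = 0.0,
    seed: int = 0,
    p_persistent: float = 0.0,
) -> MaskPlan:
    """Full masking plan for a benchmark run.

    If ``table`` already contains true missing cells those ARE the persistent
    set (no truth is known for them); otherwise a persistent set is drawn
    with probability ``p_persistent``.
    """
    real = missing_cells(table)
    truth: dict[CellRef, float] = {}
    if real:
        persistent = real
    else:
        persistent = make_persistent_mask(table, p_persistent, mechanism, shape, seed)
        for c in sorted(persistent):
            truth[c] = float(table.values[c.row_index, c.col_index])
    diagnostic = make_diagnostic_masks(table, persistent, p_miss, k, mechanism, shape, seed)
    for cells in diagnostic:
        for c in sorted(cells):
            truth[c] = float(table.values[c.row_index, c.col_index])
    plan = MaskPlan(
        persistent=persistent,
        diagnostic=diagnostic,
        truth=truth,
        p_miss=p_miss,
        mechanism=mechanism,
        seed=seed,
        p_persistent=p_persistent,
    )
    plan.validate()
    return plan
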