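"""Poisoned (negative-benchmark) and calibrating (noise-ladder) references.

These pseudo-imputers consult the hidden truth of a masked cell and return
a deliberately distorted (poisoned) or noise-perturbed (calibrating) value.
They anchor the ranking: if a poisoned method ranks among the best genuine
imputers, the dataset is flagged as not reliably imputable; the tinyNoise_c
ladder situates genuine methods on a graded accuracy scale.

The column scale ``E = median(|observed values|)`` is computed from the
masked table's observed cells, so references never see more truth than the
single value they replace.  Every formula falls back to the constant 1 when
``E = 0``.
"""

from __future__ import annotations

import numpy as np

from .tabular import CellRef, NumericTable

__all__ = [
    "scale_estimate", "poison_plus", "poison_factor", "poison_plusminus",
    "calibrate_tinynoise", "TINYNOISE_GRID", "fill_reference",
]

#: noise half-width grid of the calibrating ladder
TINYNOISE_GRID = (1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)

DEFAULT_C = {"plus": 0.5, "factor": 0.5, "plusminus": 0.1}


def scale_estimate(column_values) -> float:
    """Robust column scale: median of absolute observed values."""
    vals = np.asarray(column_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 1:
        raise ValueError("scale estimate needs at least one observed value")
    return float(np.median(np.abs(vals)))


def poison_plus(y: float, scale: float, c: float) -> float:
    """Additive bias: ``y + c*E`` (1 when E = 0)."""
    if c == 0:
        raise ValueError("c must be nonzero")
    return y + c * scale if scale != 0 else 1.0


def poison_factor(y: float, scale: float, c: float) -> float:
    """Multiplicative bias: ``y * (1 + c)`` (1 when E = 0)."""
    if c == 0:
        raise ValueError("c must be nonzero")
    return y * (1.0 + c) if scale != 0 else 1.0


def poison_plusminus(y: float, scale: float, c: float, position: int) -> float:
    """Alternating bias: ``y + (-1)^i * (1 + c) * E`` (1 when E = 0).

    ``position`` is the 0-based ordinal of the masked cell within its
    column's masked set, row-ascending; consecutive cells are pushed up and
    down symmetrically so the expected value is unchanged.
    """
    if c == 0:
        raise ValueError("c must be nonzero")
    if scale == 0:
        return 1.0
    return y + ((-1.0) ** position) * (1.0 + c) * scale


def calibrate_tinynoise(y: float, scale: float, c: float, rng: np.random.Generator) -> float:
    """Truth plus uniform noise on ``[-c*E, +c*E]`` (1 when E = 0)."""
    if not c > 0:
        raise ValueError("c must be positive")
    if scale == 0:
        return 1.0
    return y + rng.uniform(-c, c) * scale


def fill_reference(
    table: NumericTable,
    truth: dict[CellRef, float],
    kind: str,
    c: float,
    seed: int = 0,
) -> NumericTable:
    """Apply a reference pseudo-method to every cell with known truth.

    ``table`` is the masked table; only cells present in ``truth`` are
    filled (references are evaluation devices, not final imputers).
    """
    out = table.copy()
    rng = np.random.default_rng(seed)
    by_col: dict[int, list[CellRef]] = {}
    for cell in truth:
        by_col.setdefault(cell.col_index, []).append(cell)
    for j in sorted(by_col):
        scale = scale_estimate(table.column(j))
        cells = sorted(by_col[j], key=lambda cc: cc.row_index)
        for i, cell in enumerate(cells):
            y = truth[cell]
            if kind == "plus":
                v = poison_plus(y, scale, c)
            elif kind == "factor":
                v = poison_factor(y, scale, c)
            elif kind == "plusminus":
                v = poison_plusminus(y, scale, c, i)
            elif kind == "tinynoise":
                v = calibrate_tinynoise(y, scale, c, rng)
            else:
                raise ValueError(f"unknown reference kind {kind!r}")
            out.values[cell.row_index, cell.col_index] = v
    return out
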