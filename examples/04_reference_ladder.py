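"""Poisoned references and the tinyNoise calibration ladder.

Masks a block of cells, applies the three poisoned pseudo-methods and the
ten tinyNoise_c rungs to the hidden truth, and prints each reference's
zDelta (mean |imputed - true| in column-sd units).  The ladder grows
monotonically with c and anchors an absolute accuracy scale; the poisoned
rows show the error level a deliberately biased filler produces — any
genuine imputer worth using must beat them.
"""

import numpy as np

from imputerank import NumericTable, apply_mask
from imputerank.references import TINYNOISE_GRID, fill_reference
from imputerank.tabular import CellRef

rng = np.random.default_rng(0)
table = NumericTable(rng.normal(10.0, 2.0, size=(80, 3)), col_ids=["a", "b", "c"])
cells = {CellRef(i, j) for i in range(0, 24) for j in range(3)}
masked, truth = apply_mask(table, cells)
sd = table.values.std(axis=0, ddof=1)


def mean_zdelta(filled):
    errs = [abs(filled.values[c.row_index, c.col_index] - truth[c]) / sd[c.col_index]
            for c in truth]
    return float(np.mean(errs))


print(f"{'reference':>22} {'zDelta':>10}")
for c in TINYNOISE_GRID:
    filled = fill_reference(masked, truth, "tinynoise", c, seed=1)
    print(f"{'tinyNoise_' + np.format_float_positional(c, trim='-'):>22} "
          f"{mean_zdelta(filled):>10.6f}")
for kind, c in (("plus", 0.5), ("factor", 0.5), ("plusminus", 0.1)):
    filled = fill_reference(masked, truth, kind, c, seed=1)
    print(f"{kind:>22} {mean_zdelta(filled):>10.6f}")
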