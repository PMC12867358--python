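"""Synthetic benchmark table generators.

Three controlled structures probe different imputation regimes: an X-shaped
pair of intersecting linear relationships (structure a multivariate method
can exploit), three independent uniform variables (pure noise, where
nothing should beat univariate fills), and seven well-separated Gaussian
clusters in 3-D (a clustering benchmark whose labels are returned for
downstream use).
"""

from __future__ import annotations

import numpy as np

from .tabular import NumericTable

__all__ = ["gen_two_linear_xy", "gen_uniform_independent", "gen_hepta"]

DEFAULT_N = 500
DEFAULT_NOISE_SD = 0.05


def gen_two_linear_xy(
    n_points: int = DEFAULT_N, noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0
) -> NumericTable:
    """X-shaped pattern: half the rows on y = x, half on y = -x, with
    x uniform on [-1, 1]; z = x plus independent noise.  Gaussian noise of
    sd ``noise_sd`` is added to y and z."""
    if n_points % 2 != 0:
        raise ValueError("n_points must be even")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1.0, 1.0, size=n_points)
    sign = np.repeat([1.0, -1.0], n_points // 2)
    y = sign * x + rng.normal(0.0, noise_sd, size=n_points)
    z = x + rng.normal(0.0, noise_sd, size=n_points)
    return NumericTable(np.column_stack([x, y, z]), col_ids=["x", "y", "z"])


def gen_uniform_independent(n_points: int = DEFAULT_N, seed: int = 0) -> NumericTable:
    """Three i.i.d. uniform[0, 1] variables: pure noise, no cross-variable
    structure for a multivariate method to exploit."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.0, 1.0, size=(n_points, 3))
    return NumericTable(vals, col_ids=["u1", "u2", "u3"])


HEPTA_CENTERS = np.array(
    [
        [0.0, 0.0, 0.0],
        [3.0, 0.0, 0.0], [-3.0, 0.0, 0.0],
        [0.0, 3.0, 0.0], [0.0, -3.0, 0.0],
        [0.0, 0.0, 3.0], [0.0, 0.0, -3.0],
    ]
)
HEPTA_SD = 0.3


def gen_hepta(n_points: int = 700, seed: int = 0) -> tuple[NumericTable, np.ndarray]:
    """Seven well-separated isotropic Gaussian clusters (sd 0.3) at the
    origin and the six axis points (+-3, 0, 0), (0, +-3, 0), (0, 0, +-3);
    sizes as equal as possible.  Returns (table, cluster labels)."""
    if n_points < 70:
        raise ValueError("n_points must be >= 70")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_points, 7)
    sizes = [base + (1 if c < extra else 0) for c in range(7)]
    labels = np.repeat(np.arange(7), sizes)
    vals = HEPTA_CENTERS[labels] + rng.normal(0.0, HEPTA_SD, size=(n_points, 3))
    table = NumericTable(vals, col_ids=["d1", "d2", "d3"])
    return table, labels
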