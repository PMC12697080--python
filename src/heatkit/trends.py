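"""Mann-Kendall trend test and Sen's slope for yearly index series.

Normal approximation with the tie-corrected variance and a +-1 continuity
correction; no pre-whitening for serial correlation. Missing values are
dropped while preserving their time positions, so Sen's slope divides by
the actual year gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = ["TrendResult", "mann_kendall", "sens_slope"]


@dataclass(frozen=True)
class TrendResult:
    s_statistic: int
    var_s: float
    z: float
    p_value: float
    slope: float
    significant: bool
    alpha: float
    n: int


def _clean(y, x=None):
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(len(y), dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    keep = np.isfinite(y)
    return y[keep], x[keep]


def sens_slope(y, x=None) -> float:
    """Median of all pairwise slopes (y_j - y_i) / (x_j - x_i), i < j."""
    y, x = _clean(y, x)
    n = len(y)
    if n < 2:
        raise InsufficientDataError("Sen's slope requires n >= 2")
    iu, ju = np.triu_indices(n, k=1)
    dx = x[ju] - x[iu]
    dy = y[ju] - y[iu]
    valid = dx != 0
    if not valid.any():
        raise InsufficientDataError("no pairs with distinct time positions")
    return float(np.median(dy[valid] / dx[valid]))


def mann_kendall(y, alpha: float = 0.05, x=None) -> TrendResult:
    """Two-sided Mann-Kendall test with Sen's slope.

    S = sum_{i<j} sign(y_j - y_i); Var(S) includes the tie correction;
    z applies the +-1 continuity correction; p from the standard normal.
    A constant series returns S=0, p=1, slope=0.
    """
    y, x = _clean(y, x)
    n = len(y)
    if n < 4:
        raise InsufficientDataError(f"Mann-Kendall requires n >= 4, got {n}")

    iu, ju = np.triu_indices(n, k=1)
    s = int(np.sum(np.sign(y[ju] - y[iu])))

    # tie correction over groups of equal values
    _, counts = np.unique(y, return_counts=True)
    tie_term = np.sum(counts * (counts - 1) * (2 * counts + 5))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    if var_s == 0 or s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var_s)
    else:
        z = (s + 1) / np.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(p, 1.0)

    if np.all(y == y[0]):
        slope = 0.0
    else:
        slope = sens_slope(y, x)
    return TrendResult(
        s_statistic=s,
        var_s=float(var_s),
        z=float(z),
        p_value=p,
        slope=slope,
        significant=bool(p < alpha),
        alpha=alpha,
        n=n,
    )
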