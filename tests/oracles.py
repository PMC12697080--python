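"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own implementations: day-by-day
scanning, manual sort-and-interpolate percentiles, O(n^2)/O(n!) direct
enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_heatwave_scan(tmax, thresholds, min_duration):
    """Day-by-day scanner: maximal runs of tmax > threshold with length
    >= min_duration, as (start_idx, end_idx, duration, peak, mean) tuples."""
    events = []
    run = []
    for i, (v, t) in enumerate(zip(tmax, thresholds)):
        if v > t:
            run.append(i)
        else:
            if len(run) >= min_duration:
                seg = [tmax[j] for j in run]
                events.append(
                    (run[0], run[-1], len(run), max(seg), sum(seg) / len(seg))
                )
            run = []
    if len(run) >= min_duration:
        seg = [tmax[j] for j in run]
        events.append((run[0], run[-1], len(run), max(seg), sum(seg) / len(seg)))
    return events


def type7_percentile(values, q):
    """Manual linear-interpolation (type 7) percentile on a sorted copy."""
    xs = sorted(values)
    n = len(xs)
    h = (n - 1) * q / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def pairwise_slopes_median(y):
    """Sen's slope by explicit O(n^2) enumeration over index positions."""
    slopes = []
    for i in range(len(y)):
        for j in range(i + 1, len(y)):
            slopes.append((y[j] - y[i]) / (j - i))
    return float(np.median(slopes))


def mk_s(y):
    s = 0
    for i in range(len(y)):
        for j in range(i + 1, len(y)):
            s += (y[j] > y[i]) - (y[j] < y[i])
    return s


def mk_exact_null_distribution(n):
    """Null distribution of S over all n! orderings of distinct ranks."""
    counts: dict[int, int] = {}
    for perm in itertools.permutations(range(n)):
        s = mk_s(perm)
        counts[s] = counts.get(s, 0) + 1
    total = math.factorial(n)
    return {s: c / total for s, c in counts.items()}


def mk_exact_two_sided_p(s_obs, null_dist):
    return sum(p for s, p in null_dist.items() if abs(s) >= abs(s_obs))


def ols_slope(y):
    """Least-squares slope against index positions."""
    x = np.arange(len(y), dtype=float)
    return float(np.polyfit(x, np.asarray(y, dtype=float), 1)[0])
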