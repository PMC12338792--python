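"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy's peak/rank/ANOVA machinery so that the
implementation and its checks never share a code path.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy.stats import f as f_dist


def brute_peaks(x, noise_floor, prominence):
    """Local maxima above the floor with topographic prominence >= threshold,
    by direct scanning; plateaus report their shallowest index."""
    x = np.asarray(x, dtype=float)
    n = x.size
    peaks = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:  # true local max (plateau [i, j])
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    out = []
    for p in peaks:
        # walk left/right to the nearest strictly higher terrain (or border),
        # tracking the minimum along the way; prominence is peak height minus
        # the higher of the two minima.
        left_min = x[p]
        k = p - 1
        while k >= 0 and x[k] <= x[p]:
            left_min = min(left_min, x[k])
            k -= 1
        right_min = x[p]
        k = p + 1
        while k < n and x[k] <= x[p]:
            right_min = min(right_min, x[k])
            k += 1
        prom = x[p] - max(left_min, right_min)
        if prom >= prominence and x[p] > noise_floor:
            out.append(p)
    return out


def enumerate_mannwhitney(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of the
    pooled (tie-free) values to the first sample. Returns (U_a, p)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n_a, n_b = len(a), len(b)

    def u_of(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y)

    u_obs = u_of(a, b)
    us = []
    for idx in combinations(range(n_a + n_b), n_a):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(n_a + n_b) if i not in idx]
        us.append(u_of(sa, sb))
    total = comb(n_a + n_b, n_a)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def anova_f_sums_of_squares(groups):
    """One-way ANOVA (F, p) from explicit between/within sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    f_stat = (ssb / df_b) / (ssw / df_w)
    return f_stat, float(f_dist.sf(f_stat, df_b, df_w))


def ols_slope_normal_equations(x, y):
    """Straight-line slope/intercept by solving the 2x2 normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sy * sxx - sx * sxy) / det
    return slope, intercept


def quartile_fences(values, k):
    """Q1/Q3 by linear interpolation of order statistics and the k*IQR
    fences, computed from first principles."""
    v = sorted(map(float, values))
    n = len(v)

    def quantile(q):
        h = (n - 1) * q
        lo = int(h)
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr
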