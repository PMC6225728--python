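"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately share no code with ``telotrack``: plain Python loops,
union-find, and textbook formulas only.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_msd(frames, positions, n_total, mode="standard"):
    """O(N^2) double-loop time-averaged MSD.

    Returns {lag_frames: msd_value} in the squared units of ``positions``.
    standard: average over observed pairs at that lag.
    literal: sum over start indices 0..N-2-lag divided by N-1-lag.
    """
    idx = {int(f): i for i, f in enumerate(frames)}
    out = {}
    for lag in range(1, n_total):
        vals = []
        last_start = (n_total - 1 - lag) if mode == "standard" else (n_total - 2 - lag)
        for i0 in range(last_start + 1):
            if i0 in idx and (i0 + lag) in idx:
                d = np.asarray(positions[idx[i0 + lag]]) - np.asarray(positions[idx[i0]])
                vals.append(float(d @ d))
        if mode == "standard":
            if vals:
                out[lag] = sum(vals) / len(vals)
        else:
            denom = n_total - 1 - lag
            if denom > 0 and vals:
                out[lag] = sum(vals) / denom
    return out


def union_find_clusters(points, cutoff):
    """Single-linkage cluster sizes via union-find over all pairs."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(tuple(points[i]), tuple(points[j]))
            if d <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    sizes: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return sorted(sizes.values(), reverse=True)


def welch_t_test(a, b):
    """Textbook Welch t statistic, Welch-Satterthwaite df and two-sided p."""
    from scipy.stats import t as t_dist

    a = [float(x) for x in a]
    b = [float(x) for x in b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t_stat = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t_stat), df)
    return t_stat, df, p


def fgn_autocovariance(hurst, dt, lag):
    """Closed-form autocovariance of unit-coefficient fGn increments.

    For an fBm with Var X(t) = c t^(2H), increments over step dt have
    cov(lag k) = (c/2) dt^(2H) (|k+1|^2H - 2|k|^2H + |k-1|^2H); this returns
    the c = 1 value.
    """
    two_h = 2.0 * hurst
    return 0.5 * dt ** two_h * (
        abs(lag + 1) ** two_h - 2.0 * abs(lag) ** two_h + abs(lag - 1) ** two_h
    )
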