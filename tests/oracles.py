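"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive each statistic from its defining formula
with plain Python loops, sharing no code with the implementation.
"""

import math

import numpy as np


def naive_moran(x, neighbors, ids, row_standardize=False):
    """Global Moran's I by an explicit double loop over unit pairs."""
    x = np.asarray(x, dtype=float)
    n = len(ids)
    pos = {u: i for i, u in enumerate(ids)}
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for u in ids:
        d = len(neighbors[u])
        for v in neighbors[u]:
            w = (1.0 / d) if row_standardize else 1.0
            num += w * z[pos[u]] * z[pos[v]]
            s0 += w
    return (n / s0) * num / (z @ z).item()


def naive_local_moran(x, neighbors, ids, row_standardize=False):
    """Per-unit local Moran statistics by explicit loops."""
    x = np.asarray(x, dtype=float)
    n = len(ids)
    pos = {u: i for i, u in enumerate(ids)}
    z = x - x.mean()
    m2 = float(z @ z) / n
    out = np.full(n, np.nan)
    for u in ids:
        d = len(neighbors[u])
        if d == 0:
            continue
        lag = 0.0
        for v in neighbors[u]:
            w = (1.0 / d) if row_standardize else 1.0
            lag += w * z[pos[v]]
        out[pos[u]] = z[pos[u]] / m2 * lag
    return out


def brute_2sfca(pop, unit_xy, provider_xy, capacity, d0):
    """O(n*m) two-step floating catchment area with explicit loops."""
    n, m = len(pop), len(capacity)
    ratio = []
    for j in range(m):
        reached = 0.0
        for i in range(n):
            if math.dist(unit_xy[i], provider_xy[j]) <= d0:
                reached += pop[i]
        ratio.append(capacity[j] / reached if reached > 0 else 0.0)
    access = []
    for i in range(n):
        a = 0.0
        for j in range(m):
            if math.dist(unit_xy[i], provider_xy[j]) <= d0:
                a += ratio[j]
        access.append(a)
    return np.array(access), np.array(ratio)


def normal_equations_ols(X, y):
    """OLS by explicit normal equations; returns beta, bse, t, ssr."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(y)), X])
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ beta
    ssr = float(resid @ resid)
    n, p = design.shape
    sigma2 = ssr / (n - p)
    bse = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
    return beta, bse, beta / bse, ssr


def marshall_eb(events, denom, neighbors, ids):
    """Local empirical Bayes smoothing by direct formula evaluation."""
    O = np.asarray(events, dtype=float)
    P = np.asarray(denom, dtype=float)
    pos = {u: i for i, u in enumerate(ids)}
    r = O / P
    smoothed = np.empty(len(ids))
    for u in ids:
        i = pos[u]
        ref = [i] + [pos[v] for v in neighbors[u]]
        m = sum(O[j] for j in ref) / sum(P[j] for j in ref)
        psum = sum(P[j] for j in ref)
        s2 = sum(P[j] * (r[j] - m) ** 2 for j in ref) / psum
        pbar = psum / len(ref)
        a = max(0.0, s2 - m / pbar)
        noise = m / P[i]
        k = 1.0 if (a + noise) == 0 else a / (a + noise)
        smoothed[i] = k * r[i] + (1 - k) * m
    return smoothed


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters on a WGS84 mean-radius sphere."""
    r = 6371008.8
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))
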