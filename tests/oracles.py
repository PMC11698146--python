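"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the defining formulas with explicit loops,
deliberately sharing no code with the package: plain Pearson sums,
rank-then-correlate Spearman, textbook Welch t, the Benjamini–Yekutieli
step-up rule, and exact enumeration of the rank-sum permutation
distribution.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


def pearson_o(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    dx = sum((x[i] - mx) ** 2 for i in range(n))
    dy = sum((y[i] - my) ** 2 for i in range(n))
    if dx == 0 or dy == 0:
        return float("nan")
    return num / math.sqrt(dx * dy)


def loo_isc_o(data, i) -> list[float]:
    """Leave-one-out ISC for subject i of a list of (units x T) matrices."""
    n_units, n_tr = data[0].shape
    out = []
    for v in range(n_units):
        others = [data[j][v] for j in range(len(data)) if j != i]
        mean_series = [
            sum(o[t] for o in others) / len(others) for t in range(n_tr)
        ]
        out.append(pearson_o(list(data[i][v]), mean_series))
    return out


def fisher_z_o(r: float) -> float:
    clip = 1.0 - 1e-7
    return math.atanh(max(-clip, min(clip, r)))


def edge_t_o(zs: list[float]) -> float:
    e = len(zs)
    m = sum(zs) / e
    var = sum((z - m) ** 2 for z in zs) / (e - 1)
    if var == 0:
        return float("nan")
    return m / math.sqrt(var / e)


def intra_nci_o(window) -> float:
    n = window.shape[0]
    zs = []
    for a in range(n):
        for b in range(a + 1, n):
            zs.append(fisher_z_o(pearson_o(list(window[a]), list(window[b]))))
    return edge_t_o(zs)


def inter_nci_o(window, idx_a, idx_b) -> float:
    zs = []
    for a in idx_a:
        for b in idx_b:
            zs.append(fisher_z_o(pearson_o(list(window[a]), list(window[b]))))
    return edge_t_o(zs)


def welch_t_o(a, b) -> tuple[float, float]:
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)  # t CDF only; the statistic is hand-built
    return t, p


def midranks_o(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho_o(x, y) -> float:
    return pearson_o(midranks_o(list(x)), midranks_o(list(y)))


def by_stepup_o(p) -> list[float]:
    """Benjamini–Yekutieli step-up, straight from the definition."""
    m = len(p)
    c = sum(1.0 / k for k in range(1, m + 1))
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, p[i] * m * c / rank_from_top)
        prev = min(prev, val)
        q[i] = prev
    return q


def ranksum_enumeration_o(a, b):
    """Exact permutation distribution of the rank-sum of group A.

    Returns (w_obs, list of W over every group assignment). Standardizing
    w_obs by the enumeration mean/sd gives the exact-permutation Z; the
    two-sided p is the fraction of assignments at least as extreme.
    """
    pooled = list(a) + list(b)
    ranks = midranks_o(pooled)
    na = len(a)
    w_obs = sum(ranks[:na])
    ws = [
        sum(ranks[i] for i in idx)
        for idx in combinations(range(len(pooled)), na)
    ]
    return w_obs, ws


def ranksum_z_p_o(a, b) -> tuple[float, float]:
    w_obs, ws = ranksum_enumeration_o(a, b)
    mean = sum(ws) / len(ws)
    var = sum((w - mean) ** 2 for w in ws) / len(ws)
    if var == 0:
        return 0.0, 1.0
    z = (w_obs - mean) / math.sqrt(var)
    zs = [(w - mean) / math.sqrt(var) for w in ws]
    p = sum(abs(x) >= abs(z) - 1e-12 for x in zs) / len(zs)
    return z, p
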