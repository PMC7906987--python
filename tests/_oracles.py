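"""Independent brute-force re-implementations used as oracles.

Everything here is written from the textbook definitions with plain Python
loops (or a different library), deliberately sharing no code with the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats as sps


def hedges_g_brute(case, control):
    n1, n2 = len(case), len(control)
    m1 = sum(case) / n1
    m2 = sum(control) / n2
    ss1 = sum((v - m1) ** 2 for v in case)
    ss2 = sum((v - m2) ** 2 for v in control)
    sp = math.sqrt((ss1 + ss2) / (n1 + n2 - 2))
    j = 1 - 3 / (4 * (n1 + n2 - 2) - 1)
    g = j * (m1 - m2) / sp
    var = (n1 + n2) / (n1 * n2) + g * g / (2 * (n1 + n2))
    return g, var


def combine_brute(gs, vars_):
    ws = [1 / v for v in vars_]
    f = sum(w * g for w, g in zip(ws, gs)) / sum(ws)
    se = math.sqrt(1 / sum(ws))
    z = f / se
    p = 2 * (1 - sps.norm.cdf(abs(z)))
    return f, se, z, p


def bh_brute(ps):
    n = len(ps)
    order = sorted(range(n), key=lambda i: ps[i])
    qs = [None] * n
    running = math.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * n / rank)
        qs[i] = min(running, 1.0)
    return qs


def sam_d_brute(values, case_idx, control_idx, s0):
    ds = []
    n1, n2 = len(case_idx), len(control_idx)
    for row in values:
        c = [row[i] for i in case_idx]
        k = [row[i] for i in control_idx]
        m1, m2 = sum(c) / n1, sum(k) / n2
        ss = sum((v - m1) ** 2 for v in c) + sum((v - m2) ** 2 for v in k)
        s = math.sqrt((1 / n1 + 1 / n2) / (n1 + n2 - 2) * ss)
        ds.append((m1 - m2) / (s + s0) if s + s0 > 0 else float("nan"))
    return ds


def sam_q_brute(values, n_case, s0):
    """Exact-enumeration SAM q-values, loops only: every label assignment,
    pooled null |d*| counts, stepwise FDR, monotone q."""
    n_genes, n = values.shape
    all_idx = list(range(n))
    d_obs = sam_d_brute(values, list(range(n_case)), list(range(n_case, n)), s0)
    null_abs = []
    n_assign = 0
    for case_idx in combinations(all_idx, n_case):
        control_idx = [i for i in all_idx if i not in case_idx]
        n_assign += 1
        for d in sam_d_brute(values, list(case_idx), control_idx, s0):
            null_abs.append(abs(d))
    fdrs = {}
    for v in {abs(d) for d in d_obs}:
        i = sum(1 for d in d_obs if abs(d) >= v)
        cnt = sum(1 for a in null_abs if a >= v)
        fdrs[v] = min(1.0, (cnt / n_assign) / i)
    qs = []
    for d in d_obs:
        qs.append(min(f for v, f in fdrs.items() if v <= abs(d)))
    return d_obs, qs


def binom_tail_brute(k, m, rate):
    return sum(math.comb(m, j) * rate**j * (1 - rate) ** (m - j)
               for j in range(k, m + 1))


def pearson_brute(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    r = num / den
    if abs(r) >= 1:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * sps.t.sf(abs(t), n - 2)


def average_ranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y):
    return pearson_brute(average_ranks(x), average_ranks(y))


def kendall_tau_b_brute(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))


def kendall_p_notie_brute(tau, n):
    """Normal-approximation two-sided p for tie-free data."""
    var = 2 * (2 * n + 5) / (9 * n * (n - 1))
    z = tau / math.sqrt(var)
    return 2 * (1 - sps.norm.cdf(abs(z)))
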