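"""Independent, deliberately naive oracle implementations used by the tests.

Everything here is loop-based and written from the defining formulas, sharing
no code with the package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def normfinder_oracle(ct: np.ndarray, groups: list[str]) -> np.ndarray:
    """Stability values from the model-based variance decomposition,
    computed with explicit loops.

    ct is samples x genes; returns one stability value per gene:
    group-averaged |shrunken bias| + SE(bias estimate).
    """
    n, k = ct.shape
    levels = sorted(set(groups))
    g_count = len(levels)

    sigma2 = {}           # (gene, group) -> intra-group variance
    ggm = {}              # (gene, group) -> gene-group mean
    for g in levels:
        rows = [i for i in range(n) if groups[i] == g]
        n_g = len(rows)
        gene_means = [sum(ct[i, j] for i in rows) / n_g for j in range(k)]
        sample_means = [sum(ct[i, j] for j in range(k)) / k for i in rows]
        total = sum(ct[i, j] for i in rows for j in range(k)) / (n_g * k)
        s2 = []
        for j in range(k):
            ss = 0.0
            for idx, i in enumerate(rows):
                r = ct[i, j] - gene_means[j] - sample_means[idx] + total
                ss += r * r
            s2.append(ss / (n_g - 1))
        mean_term = sum(s2) / (k * (k - 1))
        for j in range(k):
            if k > 2:
                v = (s2[j] - mean_term) * k / (k - 2)
            else:
                v = s2[j]
            sigma2[(j, g)] = max(v, 0.0)
            ggm[(j, g)] = gene_means[j]

    # doubly centered biases
    d = {}
    gene_overall = {j: sum(ggm[(j, g)] for g in levels) / g_count for j in range(k)}
    group_overall = {g: sum(ggm[(j, g)] for j in range(k)) / k for g in levels}
    grand = sum(gene_overall.values()) / k
    for j in range(k):
        for g in levels:
            d[(j, g)] = ggm[(j, g)] - gene_overall[j] - group_overall[g] + grand

    n_of = {g: sum(1 for x in groups if x == g) for g in levels}
    var_dhat = {(j, g): sigma2[(j, g)] / n_of[g] for j in range(k) for g in levels}
    gamma2 = sum(v * v for v in d.values()) / ((g_count - 1) * (k - 1)) - (
        sum(var_dhat.values()) / (g_count * k)
    )
    gamma2 = max(gamma2, 0.0)

    rho = np.zeros(k)
    for j in range(k):
        acc = 0.0
        for g in levels:
            if gamma2 > 0:
                shrink = gamma2 / (gamma2 + var_dhat[(j, g)])
            else:
                shrink = 0.0
            acc += abs(d[(j, g)] * shrink) + math.sqrt(var_dhat[(j, g)])
        rho[j] = acc / g_count
    return rho


def logrank_z_oracle(time_a, event_a, time_b, event_b) -> float:
    """Standardized two-group log-rank statistic, plain loops."""
    ta, ea = list(time_a), list(event_a)
    tb, eb = list(time_b), list(event_b)
    times = sorted(
        {t for t, e in zip(ta, ea) if e} | {t for t, e in zip(tb, eb) if e}
    )
    num = 0.0
    var = 0.0
    for t in times:
        na = sum(1 for x in ta if x >= t)
        nb = sum(1 for x in tb if x >= t)
        n = na + nb
        if na == 0 or nb == 0:
            continue
        da = sum(1 for x, e in zip(ta, ea) if x == t and e)
        db = sum(1 for x, e in zip(tb, eb) if x == t and e)
        dd = da + db
        num += da - dd * na / n
        if n > 1:
            var += dd * (na / n) * (nb / n) * (n - dd) / (n - 1)
    return num / math.sqrt(var) if var > 0 else math.nan


def cutpoint_oracle(expression, time, event, minprop=0.2):
    """Exhaustive enumeration of admissible midpoint cutpoints; returns
    (best cutpoint, signed z at it) maximizing |z|, ties to the smallest."""
    x = list(map(float, expression))
    n = len(x)
    min_count = max(1, math.floor(minprop * n))
    distinct = sorted(set(x))
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        c = (lo + hi) / 2.0
        left = [i for i in range(n) if x[i] <= c]
        right = [i for i in range(n) if x[i] > c]
        if len(left) < min_count or len(right) < min_count:
            continue
        z = logrank_z_oracle(
            [time[i] for i in left], [event[i] for i in left],
            [time[i] for i in right], [event[i] for i in right],
        )
        if math.isnan(z):
            continue
        if best is None or abs(z) > abs(best[1]) + 1e-12:
            best = (c, z)
    return best


def cox_efron_loglik_oracle(beta: float, x, time, event) -> float:
    """Efron partial log-likelihood of a single covariate, plain loops."""
    n = len(x)
    theta = [math.exp(beta * xi) for xi in x]
    ll = 0.0
    for t in sorted({time[i] for i in range(n) if event[i]}):
        dead = [i for i in range(n) if time[i] == t and event[i]]
        risk = [i for i in range(n) if time[i] >= t]
        d = len(dead)
        sum_risk = sum(theta[i] for i in risk)
        sum_dead = sum(theta[i] for i in dead)
        for i in dead:
            ll += beta * x[i]
        for l in range(d):
            ll -= math.log(sum_risk - (l / d) * sum_dead)
    return ll


def cox_grid_oracle(x, time, event, lo=-4.0, hi=4.0, steps=8001) -> float:
    """Grid-search maximizer of the Efron partial likelihood."""
    grid = np.linspace(lo, hi, steps)
    vals = [cox_efron_loglik_oracle(b, x, time, event) for b in grid]
    return float(grid[int(np.argmax(vals))])


def km_oracle(time, event):
    """Product-limit curve by direct multiplication; returns dict t -> S(t)."""
    out = {}
    s = 1.0
    for t in sorted({t for t, e in zip(time, event) if e}):
        at_risk = sum(1 for x in time if x >= t)
        d = sum(1 for x, e in zip(time, event) if x == t and e)
        s *= (at_risk - d) / at_risk
        out[t] = s
    return out


def bh_oracle(pvals):
    """Step-up Benjamini-Hochberg from the textbook formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    for rank, i in enumerate(order, start=1):
        adj[i] = min(1.0, min(
            m * pvals[j] / (r)
            for r, j in enumerate(order, start=1) if r >= rank
        ))
    return adj
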