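"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — enumeration, tabular bookkeeping,
dense eigensolvers — and shares no code with the package paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import minimize_scalar


def bh_adjust(p):
    """Benjamini–Hochberg by definition: adj_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = running
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def ranksum_exact_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)
    ranks = _rank(pooled)

    def u_from_idx(idx):
        r1 = sum(ranks[i] for i in idx)
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_from_idx(range(n1))
    us = [u_from_idx(c) for c in combinations(range(len(pooled)), n1)]
    us = np.asarray(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def _rank(values):
    """Midranks."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_v = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def components_union_find(nodes, edges):
    """Connected components via union-find; returns a list of frozensets."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in edges:
        if u in parent and v in parent:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]


def breslow_loglik(beta, x, time, event):
    """Breslow partial log-likelihood evaluated directly from its definition."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_mle_grid(x, time, event, bound=10.0):
    """Maximiser of the Breslow partial likelihood by 1-D numerical optimisation."""
    res = minimize_scalar(
        lambda b: -breslow_loglik(b, x, time, event),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def logrank_chi2(time_a, event_a, time_b, event_b):
    """Two-group log-rank chi-square from the observed-minus-expected table."""
    time_a, event_a = np.asarray(time_a, float), np.asarray(event_a, int)
    time_b, event_b = np.asarray(time_b, float), np.asarray(event_b, int)
    times = np.unique(np.concatenate([time_a[event_a == 1], time_b[event_b == 1]]))
    o_minus_e, var = 0.0, 0.0
    for t in times:
        n1 = np.sum(time_a >= t)
        n2 = np.sum(time_b >= t)
        d1 = np.sum((time_a == t) & (event_a == 1))
        d2 = np.sum((time_b == t) & (event_b == 1))
        n, d = n1 + n2, d1 + d2
        if n < 1 or d < 1:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e**2) / var


def km_survival_at(time, event, t_query):
    """Product-limit estimate S(t_query) from the tabular definition."""
    time, event = np.asarray(time, float), np.asarray(event, int)
    s = 1.0
    for t in np.unique(time[event == 1]):
        if t > t_query:
            break
        n_at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / n_at_risk
    return s


def ks_statistic(values, cdf):
    """sup_x |ECDF(x) − F(x)| evaluated at the jump points."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    f = np.array([cdf(v) for v in values])
    upper = np.max(np.arange(1, n + 1) / n - f)
    lower = np.max(f - np.arange(0, n) / n)
    return max(upper, lower)


def pca_scores_eigh(values, n_components=2):
    """PC scores from a dense eigendecomposition of the gene covariance.

    Centres each gene, forms the samples × samples Gram matrix of the
    centred data and eigendecomposes it (equivalent to the gene-space
    covariance route, independent of SVD).  Signs are aligned to a
    nonnegative loading sum, matching the package convention.
    """
    v = np.asarray(values, dtype=float)
    c = v - v.mean(axis=1, keepdims=True)
    gram = c.T @ c
    w, vec = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1][:n_components]
    scores = vec[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    for k in range(scores.shape[1]):
        denom = np.sqrt(np.maximum(w[order][k], 1e-300))
        loading = c @ vec[:, order[k]] / denom
        if loading.sum() < 0:
            scores[:, k] *= -1.0
    return scores
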