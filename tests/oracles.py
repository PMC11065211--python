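"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity from its textbook definition, in a
deliberately naive style disjoint from the package's implementations.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
import scipy.stats


def trace_match(score_by_id: dict, group_by_id: dict, caliper=0.2, ratio=1,
                focal_group_on_tie=1, order="ascending"):
    """Literal step-by-step trace of the stepwise matching flow chart.

    Full scans over plain dicts, no shared code with the matcher. Returns
    (pairs, excluded focal ids, unused candidate ids).
    """
    groups = set(group_by_id.values())
    assert groups == {0, 1}
    n = {g: sum(1 for v in group_by_id.values() if v == g) for g in (0, 1)}
    if n[0] == n[1]:
        focal_group = focal_group_on_tie
    elif n[0] < n[1]:
        focal_group = 0
    else:
        focal_group = 1
    focal = [(score_by_id[i], i) for i in group_by_id if group_by_id[i] == focal_group]
    focal.sort(reverse=(order == "descending"))
    available = {i for i in group_by_id if group_by_id[i] != focal_group}

    pairs, excluded = [], []
    for fscore, fid in focal:
        chosen = []
        failed = False
        for _ in range(ratio):
            best = None
            for cid in sorted(available):
                d = abs(score_by_id[cid] - fscore)
                key = (d, score_by_id[cid], cid)
                if best is None or key < best:
                    best = key
            if best is None or best[0] >= caliper:
                failed = True
                break
            available.discard(best[2])
            chosen.append(best[2])
        if failed:
            for cid in chosen:  # provisional picks go back to the pool
                available.add(cid)
            excluded.append(fid)
        else:
            pairs.append((fid, tuple(chosen)))
    return pairs, excluded, sorted(available)


def logit_negloglik(beta, X, y):
    """Exact binomial negative log-likelihood at beta (first entry b0)."""
    eta = X @ beta
    return float(np.sum(np.log1p(np.exp(eta))) - y @ eta)


def brute_force_logit(X, y, x0=None):
    """Minimize the exact negative log-likelihood with Nelder-Mead + BFGS."""
    x0 = np.zeros(X.shape[1]) if x0 is None else x0
    r1 = scipy.optimize.minimize(logit_negloglik, x0, args=(X, y), method="BFGS",
                                 options={"gtol": 1e-10, "maxiter": 5000})
    r2 = scipy.optimize.minimize(logit_negloglik, r1.x, args=(X, y),
                                 method="Nelder-Mead",
                                 options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000})
    best = min((r1, r2), key=lambda r: r.fun)
    return best.x, -best.fun


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def pooled_t_pvalue(x, y):
    """Closed-form pooled-variance t-test: statistic + t CDF."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    return t, 2 * scipy.stats.t.sf(abs(t), df)


def yates_chi2_pvalue(table):
    """Hand formula: sum(max(0, |O - E| - 0.5)^2 / E), 1 df survival function."""
    t = np.asarray(table, float)
    rows, cols, n = t.sum(1), t.sum(0), t.sum()
    E = np.outer(rows, cols) / n
    stat = np.sum(np.maximum(np.abs(t - E) - 0.5, 0.0) ** 2 / E)
    return stat, scipy.stats.chi2.sf(stat, 1)
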