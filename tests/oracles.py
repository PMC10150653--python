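"""Independent brute-force oracles used by the test suite.

Each function recomputes a statistic by direct enumeration or an explicit
loop, sharing no code with the implementation it checks.
"""

from itertools import combinations, product

import numpy as np
import scipy.stats


def loop_score(values, obs_ids, gene_ids, positive, negative=None, mean=False):
    """Per-observation signature score via an explicit per-cell loop."""
    out = {}
    gidx = {g: j for j, g in enumerate(gene_ids)}
    for i, obs in enumerate(obs_ids):
        if mean:
            present = [g for g in positive if g in gidx]
            out[obs] = sum(values[i][gidx[g]] for g in present) / len(present)
        else:
            out[obs] = sum(values[i][gidx[g]] for g in positive) - sum(
                values[i][gidx[g]] for g in (negative or [])
            )
    return out


def mann_whitney_enumeration_p(x, y):
    """Exact two-tailed Mann-Whitney p by enumerating every assignment of
    the pooled ranks to the first group (requires no ties)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    n1 = len(x)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - n1 * (n1 + 1) / 2
    us = [
        sum(idx) - n1 * (n1 + 1) / 2
        for idx in combinations(range(1, len(pooled) + 1), n1)
    ]
    us = np.array(us, dtype=float)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_sign_enumeration_p(x, y):
    """Exact two-tailed Wilcoxon signed-rank p by enumerating all 2^n sign
    patterns over the nonzero differences (midranks handle tied |d|)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = scipy.stats.rankdata(np.abs(d))
    r_plus_obs = ranks[d > 0].sum()
    r_minus_obs = ranks[d < 0].sum()
    w_obs = min(r_plus_obs, r_minus_obs)
    r_plus_all = [
        sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=n)
    ]
    p = np.mean(np.asarray(r_plus_all) <= w_obs)
    return min(1.0, 2.0 * p)


def spearman_rank_formula(x, y):
    """r = 1 - 6 * sum(d_i^2) / (n (n^2 - 1)); valid only without ties."""
    x, y = np.asarray(x), np.asarray(y)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    n = len(x)
    return 1.0 - 6.0 * float(np.sum((rx - ry) ** 2)) / (n * (n * n - 1))


def groupby_loop_summary(emt, mcam, sinv, scsc):
    """Nine-cell summary via an explicit dict-of-lists loop."""
    groups: dict[tuple, list] = {}
    for e, m, a, b in zip(emt, mcam, sinv, scsc):
        groups.setdefault((e, m), []).append((a, b))
    out = {}
    for key, vals in groups.items():
        arr = np.array(vals)
        out[key] = (len(vals), arr[:, 0].mean(), arr[:, 1].mean())
    return out
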