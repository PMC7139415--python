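"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (loops, exhaustive enumeration) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def growth_index_naive(d0, d6, n6):
    return (d6 - n6) / d0


def success_rate_naive(rates):
    vals = [r for r in rates if r == r]  # drop NaN
    return sum(1 for r in vals if r > 1) / len(vals), len(vals)


def bh_naive(pvals):
    """Step-up: q at sorted position k is min_{j>=k} m*p_(j)/j, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    sp = [pvals[i] for i in order]
    qs = [min(1.0, min(m * sp[j] / (j + 1) for j in range(k, m))) for k in range(m)]
    out = [0.0] * m
    for k, i in enumerate(order):
        out[i] = qs[k]
    return out


def wilcoxon_exact_naive(x, y):
    """Two-sided exact rank-sum p by enumerating every group assignment."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(n + m), n):
        r = sum(ranks[pooled[i]] for i in combo)
        us.append(r - n * (n + 1) / 2)
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(lo, hi))


def pearson_naive(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def ward_partition_naive(points: np.ndarray, k: int) -> list[set[int]]:
    """Greedy agglomeration recomputing every pairwise Ward cost per merge.

    Ward cost of merging A and B is the increase in total within-cluster
    sum of squares: |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2.
    """
    clusters = [{i} for i in range(len(points))]
    while len(clusters) > k:
        best, best_cost = None, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a = points[list(clusters[i])]
                b = points[list(clusters[j])]
                ca, cb = a.mean(axis=0), b.mean(axis=0)
                cost = len(a) * len(b) / (len(a) + len(b)) * float(((ca - cb) ** 2).sum())
                if best_cost is None or cost < best_cost:
                    best, best_cost = (i, j), cost
        i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def fisher_exact_naive(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        return (
            math.comb(r1, a_) * math.comb(r2, c1 - a_) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def ssgsea_naive(values, gene_in_set, alpha=0.25):
    """Hand evaluation of the rank-weighted ECDF difference sum for one
    sample: values and membership aligned, genes in matrix order."""
    n = len(values)
    order = sorted(range(n), key=lambda i: -values[i])
    rank_value = [n - pos for pos in range(n)]
    in_sorted = [gene_in_set[i] for i in order]
    w = [rank_value[pos] ** alpha if in_sorted[pos] else 0.0 for pos in range(n)]
    wsum = sum(w)
    n_out = n - sum(gene_in_set)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for pos in range(n):
        cum_in += w[pos] / wsum
        cum_out += (0 if in_sorted[pos] else 1) / n_out
        score += cum_in - cum_out
    return score


def gsea_es_naive(metric_sorted, in_sorted, weight=1.0):
    """Running-sum extremum on an already-sorted metric."""
    w = [abs(m) ** weight for m in metric_sorted]
    hit_total = sum(wi for wi, s in zip(w, in_sorted) if s)
    miss_total = sum(1 for s in in_sorted if not s)
    run, best = 0.0, 0.0
    for wi, s in zip(w, in_sorted):
        run += wi / hit_total if s else -1.0 / miss_total
        if abs(run) > abs(best):
            best = run
    return best
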