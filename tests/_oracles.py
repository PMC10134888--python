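"""Brute-force reference implementations used only as test oracles.

Each function recomputes a statistic from its definition by direct enumeration
or closed form, independently of the library's computational path.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def midranks(values):
    """Average ranks with ties, computed by explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    if dx == 0 or dy == 0:
        return None
    return num / (dx * dy)


def spearman_oracle(x, y):
    """Mid-rank then Pearson, all by hand."""
    return pearson(midranks(list(x)), midranks(list(y)))


def wilcoxon_oracle(x, y):
    """Exact two-sided rank-sum P by enumerating the pairwise-count U statistic.

    For every assignment of the pooled values to a group of size len(x), the
    Mann-Whitney U (count of (x_i, y_j) pairs with x_i > y_j, ties counting
    one half) is computed directly; P = 2*min(P(U <= u), P(U >= u)) capped at 1.
    """
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(group):
        rest = [pooled[i] for i in range(len(pooled)) if i not in group]
        g = [pooled[i] for i in group]
        u = 0.0
        for a in g:
            for b in rest:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_stat(set(range(nx)))
    us = [u_stat(set(idx)) for idx in combinations(range(len(pooled)), nx)]
    tol = 1e-9
    p_le = sum(u <= u_obs + tol for u in us) / len(us)
    p_ge = sum(u >= u_obs - tol for u in us) / len(us)
    return min(1.0, 2.0 * min(p_le, p_ge))


def ward_heights_oracle(dist):
    """Merge heights from a direct Lance-Williams Ward.D2 agglomeration.

    ``dist`` is a full square distance matrix without tied merge candidates.
    At each step the closest active pair merges (lexicographic tie-break) and
    distances update via the squared-distance Ward recurrence.
    """
    n = dist.shape[0]
    d2 = {}
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = dist[i, j] ** 2
    heights = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for a, b in combinations(sorted(active), 2):
            key = (min(a, b), max(a, b))
            if best is None or d2[key] < d2[best] - 1e-15:
                best = key
        i, j = best
        heights.append(math.sqrt(d2[best]))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            dij = d2[(i, j)]
            d2[(min(new, k), max(new, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        active = [k for k in active if k not in (i, j)] + [new]
        sizes[new] = ni + nj
    return heights


def connectivity_oracle(dist, labels, neighbors):
    total = 0.0
    n = len(labels)
    for i in range(n):
        others = sorted(
            (j for j in range(n) if j != i), key=lambda j: (dist[i, j], j)
        )
        for rank, j in enumerate(others[:neighbors], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def silhouette_oracle(dist, labels):
    """Mean silhouette width from the definition; singleton clusters get 0."""
    n = len(labels)
    widths = []
    for i in range(n):
        own = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not own:
            widths.append(0.0)
            continue
        a = sum(dist[i, j] for j in own) / len(own)
        b = math.inf
        for lab in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == lab]
            b = min(b, sum(dist[i, j] for j in members) / len(members))
        widths.append((b - a) / max(a, b))
    return sum(widths) / n


def dunn_oracle(dist, labels):
    n = len(labels)
    between = math.inf
    within = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                within = max(within, dist[i, j])
            else:
                between = min(between, dist[i, j])
    return math.inf if within == 0 else between / within


def ols_oracle(x, y):
    """Closed-form two-parameter least squares: slope, intercept, R²."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    sse = sum((b - (intercept + slope * a)) ** 2 for a, b in zip(x, y))
    sst = sum((b - my) ** 2 for b in y)
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    return slope, intercept, r2


def jsd_oracle(p, q):
    """Term-by-term summation of the two KL components, natural log."""
    m = [(a + b) / 2.0 for a, b in zip(p, q)]

    def kl(u, v):
        total = 0.0
        for a, b in zip(u, v):
            if a > 0:
                total += a * math.log(a / b)
        return total

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)
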