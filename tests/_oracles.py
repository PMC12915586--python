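"""Independent brute-force oracles used to verify the implementation.

These are deliberately naive: plain nested-loop dynamic programming, full
permutation enumeration, and direct textbook formulas. They share only the
documented conventions (scoring model, tie-breaks) with the package, not
its code paths.
"""
from __future__ import annotations

import itertools
import math


def oracle_align(query: str, subject: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Overlap alignment by exhaustive DP with the documented tie-breaks.

    Returns (score, identity_pct, query_coverage_pct, alignment_length).
    """
    m, n = len(query), len(subject)

    def sub(i, j):
        a, b = query[i - 1], subject[j - 1]
        return match if (a == b and a != "N") else mismatch

    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            H[i][j] = max(
                H[i - 1][j - 1] + sub(i, j),
                H[i - 1][j] + gap,
                H[i][j - 1] + gap,
            )
    # end cell: first strict max over last row (j ascending), then last column
    best_i, best_j, best = m, 0, H[m][0]
    for j in range(1, n + 1):
        if H[m][j] > best:
            best, best_i, best_j = H[m][j], m, j
    for i in range(m):
        if H[i][n] > best:
            best, best_i, best_j = H[i][n], i, n
    i, j = best_i, best_j
    end_i = i
    cols = matches = 0
    while i > 0 and j > 0:
        if H[i][j] == H[i - 1][j - 1] + sub(i, j):
            if query[i - 1] == subject[j - 1] and query[i - 1] != "N":
                matches += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
        cols += 1
    if cols == 0:
        return best, 0.0, 0.0, 0
    return best, 100.0 * matches / cols, 100.0 * (end_i - i) / m, cols


def oracle_spearman(x, y):
    """Rank-then-Pearson rho with average ranks, no library calls."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def oracle_kruskal_h(groups):
    """Kruskal-Wallis H with tie correction via the direct formula."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    r = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            r[order[k]] = avg
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        rg = r[start : start + len(g)]
        h += sum(rg) ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    from collections import Counter

    ties = Counter(pooled)
    corr = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return 0.0 if corr == 0 else h / corr


def oracle_mantel_enumeration(d1, d2):
    """Exact Mantel p by full enumeration of all n! relabelings of d2.

    Pearson correlation over the strictly-lower triangle; p is the fraction
    of relabelings with R >= R_observed (identity included).
    """
    n = len(d1)

    def tri(d):
        return [d[i][j] for i in range(n) for j in range(i)]

    def pearson(a, b):
        k = len(a)
        ma, mb = sum(a) / k, sum(b) / k
        num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        den = math.sqrt(sum((x - ma) ** 2 for x in a) * sum((y - mb) ** 2 for y in b))
        return num / den

    xa = tri(d1)
    r_obs = pearson(xa, tri(d2))
    count = total = 0
    for perm in itertools.permutations(range(n)):
        db = [[d2[perm[i]][perm[j]] for j in range(n)] for i in range(n)]
        if pearson(xa, tri(db)) >= r_obs:
            count += 1
        total += 1
    return r_obs, count / total


def oracle_oneway_permanova_f(d, labels):
    """Pseudo-F for a one-way design from the definitional SS formulas:
    SS_total = sum_{i<j} d_ij^2 / n, SS_within = sum_g sum_{i<j in g} d^2 / n_g.
    """
    n = len(labels)
    ss_total = sum(d[i][j] ** 2 for i in range(n) for j in range(i)) / n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(d[i][j] ** 2 for i in idx for j in idx if j < i) / len(idx)
    ss_between = ss_total - ss_within
    df_b, df_w = len(groups) - 1, n - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def oracle_indval(abund, in_a):
    """IndVal = 100 * A * B on each side, by hand."""
    a_vals = [v for v, m in zip(abund, in_a) if m]
    b_vals = [v for v, m in zip(abund, in_a) if not m]
    m_a = sum(a_vals) / len(a_vals)
    m_b = sum(b_vals) / len(b_vals)
    occ_a = sum(v > 0 for v in a_vals) / len(a_vals)
    occ_b = sum(v > 0 for v in b_vals) / len(b_vals)
    denom = m_a + m_b
    iv_a = 100.0 * (m_a / denom) * occ_a if denom else 0.0
    iv_b = 100.0 * (m_b / denom) * occ_b if denom else 0.0
    return iv_a, iv_b
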