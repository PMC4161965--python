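"""Naive loop-based reference implementations used as independent oracles.

Everything here is written for clarity, not speed: explicit Python loops and
textbook formulas, kept free of any code from the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def size_factors_naive(values):
    """Median-of-ratios size factors: the per-sample median of
    log(count) - log(geometric mean), exponentiated (median taken in log
    space, as in the reference implementation)."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    log_geo = [np.mean([math.log(values[g, s]) for s in range(n_samples)])
               for g in range(n_genes)]
    factors = []
    for s in range(n_samples):
        log_ratios = sorted(math.log(values[g, s]) - log_geo[g] for g in range(n_genes))
        factors.append(math.exp(float(np.median(log_ratios))))
    return np.array(factors)


def signal2noise_naive(values, mask):
    values = np.asarray(values, dtype=float)
    out = []
    for row in values:
        a, b = row[mask], row[~mask]
        m1, m2 = np.mean(a), np.mean(b)
        s1 = max(np.std(a, ddof=1), 0.2 * abs(m1), 1e-8)
        s2 = max(np.std(b, ddof=1), 0.2 * abs(m2), 1e-8)
        out.append((m1 - m2) / (s1 + s2))
    return np.array(out)


def gene_pvalues_naive(observed, null):
    """Leave-self-out over the pooled observed + permuted columns."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    n = null.shape[1]
    pvals = np.array(
        [sum(abs(null[g, j]) >= abs(observed[g]) for j in range(n)) / n
         for g in range(len(observed))]
    )
    perm = np.zeros_like(null)
    for g in range(len(observed)):
        for i in range(n):
            others = [abs(observed[g])] + [abs(null[g, j]) for j in range(n) if j != i]
            perm[g, i] = sum(v >= abs(null[g, i]) for v in others) / n
    return pvals, perm


# --- set statistics ---------------------------------------------------------


def weighted_ks_naive(scores, member, p=1.0):
    scores = np.asarray(scores, dtype=float)
    member = np.asarray(member, dtype=bool)
    g = len(scores)
    k = int(member.sum())
    order = sorted(range(g), key=lambda i: (-scores[i], i))
    total = sum(abs(scores[i]) ** p for i in order if member[i])
    running = 0.0
    mx, mn = -np.inf, np.inf
    for i in order:
        if member[i]:
            running += (abs(scores[i]) ** p / total) if total > 0 else 1.0 / k
        else:
            running -= 1.0 / (g - k)
        mx, mn = max(mx, running), min(mn, running)
    return mx if mx >= -mn else mn


def weighted_ks_extremes(scores, member, p=1.0):
    """Running-sum max and min, for detecting exact +/- deviation ties."""
    scores = np.asarray(scores, dtype=float)
    member = np.asarray(member, dtype=bool)
    g = len(scores)
    k = int(member.sum())
    order = sorted(range(g), key=lambda i: (-scores[i], i))
    total = sum(abs(scores[i]) ** p for i in order if member[i])
    running, mx, mn = 0.0, -np.inf, np.inf
    for i in order:
        if member[i]:
            running += (abs(scores[i]) ** p / total) if total > 0 else 1.0 / k
        else:
            running -= 1.0 / (g - k)
        mx, mn = max(mx, running), min(mn, running)
    return mx, mn


def l2norm_naive(scores):
    return math.sqrt(sum(s * s for s in scores))


def mean_abs_naive(scores):
    return sum(abs(s) for s in scores) / len(scores)


def sig_ratio_naive(pvals, alpha=0.05):
    return sum(1 for p in pvals if p <= alpha) / len(pvals)


def weighted_sig_ratio_naive(scores, pvals, alpha=0.05):
    return sum(abs(s) for s, p in zip(scores, pvals) if p <= alpha) / len(scores)


def geometric_mean_naive(pvals, eps=0.0):
    pvals = [max(p, eps) for p in pvals]
    return math.exp(sum(math.log(p) for p in pvals) / len(pvals))


def truncated_product_naive(pvals, tau=0.05):
    prod = 1.0
    for p in pvals:
        if p <= tau:
            prod *= p
    return prod


def fisher_naive(pvals, eps=0.0):
    pvals = [max(p, eps) for p in pvals]
    return -2.0 * sum(math.log(p) for p in pvals)


def min_p_naive(pvals):
    return min(pvals)


def significance_ranks_naive(pvals, scores):
    keys = [(pvals[i], -abs(scores[i])) for i in range(len(pvals))]
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    ranks = [0.0] * len(keys)
    pos = 0
    while pos < len(order):
        end = pos
        while end < len(order) and keys[order[end]] == keys[order[pos]]:
            end += 1
        avg = (pos + 1 + end) / 2.0  # mean of positions pos+1 .. end
        for j in range(pos, end):
            ranks[order[j]] = avg
        pos = end
    return np.array(ranks)


def rank_sum_naive(pvals, scores, member):
    ranks = significance_ranks_naive(pvals, scores)
    return float(sum(r for r, m in zip(ranks, member) if m))


# --- significance machinery -------------------------------------------------


def empirical_p_naive(as0, null, greater=True):
    if greater:
        return sum(1 for v in null if v >= as0) / len(null)
    return sum(1 for v in null if v <= as0) / len(null)


def fdr_naive(nas_obs, nas_null, greater=True):
    m, n = nas_null.shape
    out = []
    for i in range(m):
        num = 0.0
        for pi in range(n):
            hits = sum(
                1 for j in range(m)
                if (nas_null[j, pi] >= nas_obs[i] if greater else nas_null[j, pi] <= nas_obs[i])
            )
            num += hits / m
        num /= n
        den = sum(
            1 for j in range(m)
            if (nas_obs[j] >= nas_obs[i] if greater else nas_obs[j] <= nas_obs[i])
        ) / m
        out.append(min(num / den, 1.0))
    return np.array(out)


def fwer_naive(nas_obs, nas_null, greater=True):
    m, n = nas_null.shape
    out = []
    for i in range(m):
        count = 0
        for pi in range(n):
            extreme = max(nas_null[:, pi]) if greater else min(nas_null[:, pi])
            hit = extreme >= nas_obs[i] if greater else extreme <= nas_obs[i]
            count += int(hit)
        out.append(count / n)
    return np.array(out)
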