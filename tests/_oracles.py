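"""Independent brute-force / closed-form oracles used to cross-check the
package implementations.  These deliberately share no code with the
package: different solvers, naive loops, exact enumeration."""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, special, stats


def mad_scores_bruteforce(signal, na_mask, block_of):
    """Naive per-(block, sample) MAD scoring with plain loops."""
    out = np.full(signal.shape, np.nan)
    n_feat, n_samp = signal.shape
    blocks = sorted(set(block_of))
    for s in range(n_samp):
        for b in blocks:
            idx = [f for f in range(n_feat) if block_of[f] == b]
            vals = [signal[f, s] for f in idx if not na_mask[f, s]]
            if len(vals) < 2:
                continue
            med = float(np.median(vals))
            mad = float(np.median([abs(v - med) for v in vals]))
            if mad == 0:
                continue
            for f in idx:
                if not na_mask[f, s]:
                    out[f, s] = (signal[f, s] - med) / mad
    return out


def moderated_t_oracle(case, control):
    """Moderated t via the same closed forms, independently coded:
    variances by per-group ddof-1 variance pooling, the prior df by Brent
    root-finding on the trigamma moment equation."""
    n1, n2 = case.shape[0], control.shape[0]
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * case.var(axis=0, ddof=1) + (n2 - 1) * control.var(axis=0, ddof=1)) / d
    e = np.log(s2) - special.digamma(d / 2) + math.log(d / 2)
    excess = e.var(ddof=1) - special.polygamma(1, d / 2)
    if excess <= 0:
        d0, s0 = math.inf, math.exp(e.mean())
        post = np.full_like(s2, s0)
        df_tot = math.inf
    else:
        half = optimize.brentq(
            lambda y: special.polygamma(1, y) - excess, 1e-6, 1e8, xtol=1e-14
        )
        d0 = 2 * half
        s0 = math.exp(e.mean() + special.digamma(half) - math.log(half))
        post = (d0 * s0 + d * s2) / (d0 + d)
        df_tot = d0 + d
    t = (case.mean(axis=0) - control.mean(axis=0)) / np.sqrt(post * (1 / n1 + 1 / n2))
    if math.isinf(df_tot):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_tot)
    return d0, s0, t, p


def mann_whitney_auc(scores, labels):
    """AUC as the pairwise win fraction, ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hypergeom_tail_exact(N, K, n, k):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exact combinatorics."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


def complete_linkage_bruteforce(X):
    """Naive agglomerative complete linkage; returns merge heights in order.

    Ties are broken by the smallest pair of original-cluster indices.
    """
    X = np.asarray(X, float)
    clusters = [[i] for i in range(X.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dmax = max(
                    float(np.linalg.norm(X[a] - X[b]))
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or dmax < best[0] - 1e-15:
                    best = (dmax, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return np.array(heights)


def welch_t_oracle(a, b):
    """Textbook Welch t with Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def bh_oracle(p):
    """Step-up BH via the naive quadratic definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[r - 1]] * m / r for r in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q
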