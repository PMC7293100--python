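"""Independent brute-force oracles used by the test-suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package's implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def enum_posterior(emiss, trans, init):
    """HMM posteriors by exhaustive enumeration over all K^n state paths.

    ``emiss[i, k]`` = P(obs_i | state k) (linear domain), ``trans`` either a
    single (K, K) matrix or a length n-1 sequence of per-step matrices.
    Returns (gamma, loglik).
    """
    emiss = np.asarray(emiss, dtype=float)
    n, K = emiss.shape
    if np.ndim(trans) == 2:
        trans_seq = [np.asarray(trans, float)] * (n - 1)
    else:
        trans_seq = [np.asarray(t, float) for t in trans]
    total = 0.0
    gamma = np.zeros((n, K))
    for path in itertools.product(range(K), repeat=n):
        p = init[path[0]] * emiss[0, path[0]]
        for i in range(1, n):
            p *= trans_seq[i - 1][path[i - 1], path[i]] * emiss[i, path[i]]
        total += p
        for i, s in enumerate(path):
            gamma[i, s] += p
    return gamma / total, np.log(total)


def poisson_pmf(k, lam):
    out = np.exp(-lam) * lam**k
    for j in range(2, int(k) + 1):
        out /= j
    return out


def gaussian_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def ls_transitions(switch, K):
    """Per-step copying-model transition matrices: redraw uniformly with
    probability ``switch[i]`` (self included), else stay."""
    out = []
    for s in switch:
        t = np.full((K, K), s / K)
        t += (1.0 - s) * np.eye(K)
        out.append(t)
    return out


def dxy_pairs(alleles_a, alleles_b, span):
    """Mean over all cross pairs of per-bp mismatch, by double loop."""
    tot = 0.0
    n = 0
    for a in alleles_a:
        for b in alleles_b:
            tot += sum(int(x != y) for x, y in zip(a, b)) / span
            n += 1
    return tot / n


def wc_fst_site(p1, n1, p2, n2):
    """Weir & Cockerham (1984) haploid ANOVA F_ST for one biallelic site."""
    nbar = (n1 + n2) / 2.0
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / 1.0  # r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2.0)
    nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    den = msp + (nc - 1.0) * msg
    return (msp - msg) / den if den > 0 else np.nan


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, textbook procedure."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def spearman_hand(x, y):
    """Spearman rho via rank Pearson formula (average ranks for ties)."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        srt = np.asarray(v, dtype=float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and srt[j + 1] == srt[i]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def base_accuracy(truth_tracts, called_tracts, chrom_length, step=500):
    """Fraction of sampled positions with matching covered/uncovered label."""
    grid = np.arange(step // 2, chrom_length, step)

    def cov(tracts):
        mask = np.zeros(len(grid), dtype=bool)
        for s, e in tracts:
            mask |= (grid >= s) & (grid < e)
        return mask

    return float((cov(truth_tracts) == cov(called_tracts)).mean())
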