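"""Scaled forward-backward / Baum-Welch kernels shared by the HMM stages.

Three hidden-Markov models run on top of these kernels: the 2-state Poisson
HMM on private-variant counts (archaic-tract detection), the 3-state
Gaussian HMM on log F_ST/F_intro ratios (RI islands), and the Li &
Stephens-type haplotype-copying model (local-ancestry painting).  Numerics
use per-step scaling in the linear domain; posteriors agree with exhaustive
path enumeration to ~1e-12 on small instances (see the test-suite oracles).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "forward_backward",
    "poisson_log_emissions",
    "gaussian_log_emissions",
    "ls_posterior",
    "stationary",
]


@njit(cache=True)
def _fb_kernel(emiss, trans, init):
    n, K = emiss.shape
    alpha = np.empty((n, K))
    beta = np.empty((n, K))
    c = np.empty(n)

    s = 0.0
    for k in range(K):
        alpha[0, k] = init[k] * emiss[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for i in range(1, n):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[i - 1, j] * trans[j, k]
            alpha[i, k] = acc * emiss[i, k]
            s += alpha[i, k]
        c[i] = s
        for k in range(K):
            alpha[i, k] /= s

    for k in range(K):
        beta[n - 1, k] = 1.0
    for i in range(n - 2, -1, -1):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += trans[k, j] * emiss[i + 1, j] * beta[i + 1, j]
            beta[i, k] = acc / c[i + 1]

    gamma = alpha * beta
    for i in range(n):
        s = 0.0
        for k in range(K):
            s += gamma[i, k]
        for k in range(K):
            gamma[i, k] /= s

    xi = np.zeros((K, K))
    for i in range(n - 1):
        for j in range(K):
            for k in range(K):
                xi[j, k] += alpha[i, j] * trans[j, k] * emiss[i + 1, k] * beta[i + 1, k] / c[i + 1]

    loglik = 0.0
    for i in range(n):
        loglik += math.log(c[i])
    return gamma, xi, loglik


def forward_backward(log_emissions: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Posterior state probabilities for one observation sequence.

    Parameters are the per-step log emission matrix ``(n, K)``, the
    transition matrix and the initial distribution.  Returns
    ``(gamma, xi_sum, loglik)`` where ``gamma[i, k] = P(state_i = k | data)``
    and ``xi_sum[j, k]`` is the expected number of j->k transitions.
    """
    log_emissions = np.asarray(log_emissions, dtype=np.float64)
    # per-row shift keeps linear-domain emissions in range without changing
    # posteriors; the shift is added back to the log-likelihood
    shift = log_emissions.max(axis=1)
    emiss = np.exp(log_emissions - shift[:, None])
    gamma, xi, loglik = _fb_kernel(
        emiss, np.asarray(trans, np.float64), np.asarray(init, np.float64)
    )
    return gamma, xi, loglik + float(shift.sum())


def poisson_log_emissions(counts: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Log P(count | state) under per-state Poisson rates."""
    counts = np.asarray(counts, dtype=np.float64)
    lam = np.maximum(np.asarray(lambdas, dtype=np.float64), 1e-12)
    from scipy.special import gammaln

    return (
        counts[:, None] * np.log(lam)[None, :]
        - lam[None, :]
        - gammaln(counts + 1.0)[:, None]
    )


def gaussian_log_emissions(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    means = np.asarray(means, dtype=np.float64)
    sds = np.maximum(np.asarray(sds, dtype=np.float64), 1e-6)
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * z**2 - np.log(sds)[None, :] - 0.5 * math.log(2 * math.pi)


@njit(cache=True)
def _ls_kernel(mismatch, switch, log_e_match, log_e_mis):
    S, K = mismatch.shape
    e_match = math.exp(log_e_match)
    e_mis = math.exp(log_e_mis)
    alpha = np.empty((S, K))
    beta = np.empty((S, K))
    c = np.empty(S)

    s = 0.0
    for k in range(K):
        e = e_mis if mismatch[0, k] else e_match
        alpha[0, k] = e / K
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for i in range(1, S):
        sw = switch[i - 1]
        s = 0.0
        for k in range(K):
            e = e_mis if mismatch[i, k] else e_match
            alpha[i, k] = ((1.0 - sw) * alpha[i - 1, k] + sw / K) * e
            s += alpha[i, k]
        c[i] = s
        for k in range(K):
            alpha[i, k] /= s

    for k in range(K):
        beta[S - 1, k] = 1.0
    for i in range(S - 2, -1, -1):
        sw = switch[i]
        tot = 0.0
        for j in range(K):
            e = e_mis if mismatch[i + 1, j] else e_match
            tot += e * beta[i + 1, j]
        for k in range(K):
            e = e_mis if mismatch[i + 1, k] else e_match
            beta[i, k] = ((1.0 - sw) * e * beta[i + 1, k] + sw / K * tot) / c[i + 1]

    gamma = alpha * beta
    for i in range(S):
        s = 0.0
        for k in range(K):
            s += gamma[i, k]
        for k in range(K):
            gamma[i, k] /= s
    return gamma


def ls_posterior(
    mismatch: np.ndarray, switch: np.ndarray, mismatch_prob: float
) -> np.ndarray:
    """Posterior copying probabilities of a Li & Stephens model.

    ``mismatch[i, k]`` is 1 where the focal haplotype differs from panel
    member ``k`` at site ``i``; ``switch[i]`` is the probability that the
    copied haplotype is redrawn (uniformly over the panel, self included)
    between sites ``i`` and ``i+1``.
    """
    mismatch = np.ascontiguousarray(mismatch, dtype=np.uint8)
    switch = np.asarray(switch, dtype=np.float64)
    if not 0.0 < mismatch_prob < 1.0:
        raise ValueError("mismatch_prob must be in (0, 1)")
    return _ls_kernel(
        mismatch, switch, math.log1p(-mismatch_prob), math.log(mismatch_prob)
    )


def stationary(trans: np.ndarray) -> np.ndarray:
    """Stationary distribution of a transition matrix (left eigenvector)."""
    trans = np.asarray(trans, dtype=np.float64)
    vals, vecs = np.linalg.eig(trans.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()
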