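"""Reference-free archaic-tract detection from private-variant excesses.

A haplotype that carries an anciently introgressed segment from a divergent
donor accumulates derived alleles that the non-admixed comparison population
lacks.  Binning those private variants (1-kb bins by default) and fitting a
2-state hidden Markov model with Poisson emissions — a low "native" rate and
a high "archaic" rate, assuming constant mutation and call rates — localises
the introgressed tracts per haplotype without any donor reference genome.
Tracts are the maximal runs of bins whose archaic posterior exceeds a
threshold (0.8 by default); combining haplotypes gives F_archaic, the
fraction of haplotypes covered at each position, averaged in 50-kb windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import forward_backward, poisson_log_emissions, stationary
from .panel import GenomicWindow, HaplotypePanel

__all__ = [
    "PrivateVariantTrack",
    "ArchaicHMMModel",
    "private_counts",
    "fit_and_decode",
    "decode",
    "fit_population",
    "call_tracts",
    "coverage_per_bin",
    "window_average",
]

NATIVE, ARCHAIC = 0, 1


@dataclass
class PrivateVariantTrack:
    """Per-haplotype, per-bin counts of variants private to the focal pop."""

    hap_ids: list[str]
    counts: np.ndarray  # (n_haplotypes, n_bins)
    bin_bp: int
    chrom: str
    chrom_length: int

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class ArchaicHMMModel:
    """2-state (native, archaic) Poisson HMM; state 1 is the high-rate state."""

    transition: np.ndarray
    lambdas: np.ndarray  # (lambda_native, lambda_archaic)
    init: np.ndarray
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = False
    degenerate: bool = False

    @property
    def p_native_to_archaic(self) -> float:
        return float(self.transition[NATIVE, ARCHAIC])


def private_counts(
    panel: HaplotypePanel,
    focal_pop: str,
    reference_pop: str,
    *,
    bin_bp: int = 1000,
    chrom_length: int | None = None,
) -> PrivateVariantTrack:
    """Count, per focal haplotype and per bin, carried variants whose derived
    allele is absent from every haplotype of the reference population."""
    L = chrom_length or panel.chrom_length
    ref_rows = panel.haps(reference_pop)
    focal_rows = panel.haps(focal_pop)
    private = panel.alleles[ref_rows].max(axis=0) == 0
    n_bins = int(np.ceil(L / bin_bp)) if L else 1
    bin_idx = (panel.positions // bin_bp).astype(np.int64)
    counts = np.zeros((len(focal_rows), n_bins), dtype=np.int64)
    for i, row in enumerate(focal_rows):
        carried = private & (panel.alleles[row] == 1)
        counts[i] = np.bincount(bin_idx[carried], minlength=n_bins)
    return PrivateVariantTrack(
        hap_ids=[panel.hap_ids[r] for r in focal_rows],
        counts=counts,
        bin_bp=bin_bp,
        chrom=panel.chrom,
        chrom_length=L,
    )


def _init_model(counts: np.ndarray, p: float = 1e-3) -> ArchaicHMMModel:
    # robust label assignment: seed the native rate from the low quantile of
    # the nonzero bins (scaled down) and the archaic rate 10x higher
    nonzero = counts[counts > 0]
    base = float(np.quantile(nonzero, 0.25)) if nonzero.size else 1.0
    lam_nat = max(0.1 * base, 1e-3)
    lam_arc = 10.0 * lam_nat
    trans = np.array([[1.0 - p, p], [0.02, 0.98]])
    return ArchaicHMMModel(transition=trans, lambdas=np.array([lam_nat, lam_arc]),
                           init=stationary(trans))


def decode(counts: np.ndarray, model: ArchaicHMMModel):
    """Forward-backward posterior P(archaic) per bin under fixed parameters."""
    loge = poisson_log_emissions(np.asarray(counts), model.lambdas)
    gamma, _, loglik = forward_backward(loge, model.transition, model.init)
    return gamma[:, ARCHAIC], loglik


def fit_and_decode(
    counts: np.ndarray,
    init: ArchaicHMMModel | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[ArchaicHMMModel, np.ndarray]:
    """Baum-Welch fit of the 2-state Poisson HMM on one haplotype's bins,
    followed by the forward-backward archaic posterior.

    States are relabelled after fitting so the archaic state has the larger
    rate; a fit where the rates collapse (lambda_arc <= lambda_nat within
    1%) is flagged degenerate and should be treated as a no-call.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 1:
        raise ValueError("counts must be one haplotype's 1-D bin sequence")
    if counts.size < 100:
        raise ValueError(f"need >= 100 bins to fit, got {counts.size}")
    model = init if init is not None else _init_model(counts)
    trans = model.transition.copy()
    lam = model.lambdas.astype(float).copy()
    pi = model.init.copy()
    prev = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        loge = poisson_log_emissions(counts, lam)
        gamma, xi, loglik = forward_backward(loge, trans, pi)
        occ = gamma.sum(axis=0)
        lam = gamma.T @ counts / np.maximum(occ, 1e-12)
        trans = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
        pi = gamma[0]
        if loglik - prev < tol and n_iter > 1:
            converged = True
            break
        prev = loglik
    if lam[ARCHAIC] < lam[NATIVE]:  # label switching: order by rate
        order = np.array([1, 0])
        lam = lam[order]
        trans = trans[np.ix_(order, order)]
        pi = pi[order]
    degenerate = not lam[ARCHAIC] > lam[NATIVE] * 1.01
    fitted = ArchaicHMMModel(
        transition=trans,
        lambdas=lam,
        init=pi,
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        degenerate=degenerate,
    )
    posterior, _ = decode(counts, fitted)
    return fitted, posterior


def fit_population(
    track: PrivateVariantTrack, **kwargs
) -> tuple[list[ArchaicHMMModel], np.ndarray]:
    """Independent per-haplotype fits; degenerate haplotypes get posterior 0
    (no-call).  Chromosome-level parameters are obtained by averaging the
    per-haplotype estimates, matching the per-haplome fitting strategy."""
    models = []
    post = np.zeros_like(track.counts, dtype=float)
    for i in range(track.counts.shape[0]):
        model, p = fit_and_decode(track.counts[i], **kwargs)
        models.append(model)
        if not model.degenerate:
            post[i] = p
    return models, post


def call_tracts(
    posterior: np.ndarray, *, bin_bp: int = 1000, threshold: float = 0.8,
    hap_ids: list[str] | None = None, chrom_length: int | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Maximal runs of bins with posterior > threshold, as bp intervals."""
    posterior = np.atleast_2d(np.asarray(posterior, dtype=float))
    n_hap, n_bins = posterior.shape
    if hap_ids is None:
        hap_ids = [f"hap{i}" for i in range(n_hap)]
    out: dict[str, list[tuple[int, int]]] = {}
    for i, hap in enumerate(hap_ids):
        above = posterior[i] > threshold
        edges = np.diff(np.concatenate([[0], above.view(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        tracts = []
        for s, e in zip(starts, ends):
            lo = int(s) * bin_bp
            hi = int(e) * bin_bp
            if chrom_length is not None:
                hi = min(hi, chrom_length)
            tracts.append((lo, hi))
        out[hap] = tracts
    return out


def coverage_per_bin(
    tracts: dict[str, list[tuple[int, int]]], n_bins: int, bin_bp: int
) -> np.ndarray:
    """F_archaic per bin: fraction of haplotypes whose tract covers the bin."""
    cov = np.zeros(n_bins, dtype=float)
    for tr in tracts.values():
        for s, e in tr:
            lo = s // bin_bp
            hi = min(int(np.ceil(e / bin_bp)), n_bins)
            cov[lo:hi] += 1.0
    return cov / max(len(tracts), 1)


def window_average(
    values_per_bin: np.ndarray, bin_bp: int, windows: list[GenomicWindow]
) -> np.ndarray:
    """Average a per-bin track in (50-kb) windows."""
    out = np.empty(len(windows))
    for i, w in enumerate(windows):
        lo = w.start // bin_bp
        hi = int(np.ceil(w.end / bin_bp))
        out[i] = values_per_bin[lo:hi].mean() if hi > lo else np.nan
    return out
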