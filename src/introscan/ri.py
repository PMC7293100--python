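"""Delineation of reproductive-isolation (RI) islands.

Regions involved in RI between the two recipient lineages combine elevated
differentiation (high F_ST) with resistance to interlineage gene flow (low
F_intro).  A 3-state hidden Markov model — low (neutral), intermediate
(linked selection), high (RI) — is fitted chromosome-by-chromosome to the
log of the F_ST/F_intro ratio with Gaussian emissions, at SNP and at 50-kb
window scale.  Units are assigned a per-unit P-value 1 - P(high | data),
FDR-corrected by Benjamini-Hochberg, and units passing alpha (0.001 by
default) are merged into island intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .hmm import forward_backward, gaussian_log_emissions
from .panel import GenomicWindow

logger = logging.getLogger("introscan")

__all__ = [
    "RatioTrack",
    "RIHMMModel",
    "RIIslandSet",
    "build_ratio",
    "fit_hmm",
    "call_islands",
    "concordance",
]

LOW, INTERMEDIATE, HIGH = 0, 1, 2


@dataclass
class RatioTrack:
    """Aligned F_ST and F_intro values with their regularised ratio.

    ``scale`` is "snp" (units are SNP positions) or "window".  The
    regularisation record keeps the floor applied to F_intro (and to
    negative per-SNP F_ST) so runs are auditable.
    """

    values: np.ndarray  # the ratio
    log_values: np.ndarray
    fst: np.ndarray
    fintro: np.ndarray
    scale: str
    positions: np.ndarray | None = None  # snp scale
    windows: list[GenomicWindow] | None = None  # window scale
    eps: float = np.nan

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RIHMMModel:
    """3-state Gaussian HMM on the log ratio, means ordered low < int < high."""

    transition: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    init: np.ndarray
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = False


@dataclass
class RIIslandSet:
    """Per-unit calls plus the merged islands passing the FDR threshold."""

    table: pd.DataFrame  # state, posterior_high, p, p_adj, retained
    islands: list[tuple[int, int]]
    alpha: float
    scale: str
    chrom: str = "chr1"


def build_ratio(
    fst: np.ndarray,
    fintro: np.ndarray,
    *,
    scale: str,
    n_haplotypes: int | None = None,
    eps: float | None = None,
    positions: np.ndarray | None = None,
    windows: list[GenomicWindow] | None = None,
) -> RatioTrack:
    """Regularised F_ST / F_intro ratio track.

    F_intro is floored at the pseudocount ``eps`` (default ``1/(2 n_hap)``,
    one haplotype below detectability) before division, and negative per-SNP
    F_ST estimates are floored at 0; undefined entries stay NaN and are
    ignored by the HMM fit.
    """
    if scale not in {"snp", "window"}:
        raise ValueError("scale must be 'snp' or 'window'")
    fst = np.asarray(fst, dtype=float)
    fintro = np.asarray(fintro, dtype=float)
    if fst.shape != fintro.shape:
        raise ValueError("F_ST and F_intro tracks must be aligned")
    if not np.any(np.isfinite(fst) & np.isfinite(fintro)):
        raise ValueError("all units are undefined in at least one input track")
    if eps is None:
        if n_haplotypes is None:
            raise ValueError("give eps or n_haplotypes (for the default 1/(2n) floor)")
        eps = 1.0 / (2.0 * n_haplotypes)
    logger.info("build_ratio: scale=%s eps=%g (F_intro floor)", scale, eps)
    ratio = np.maximum(fst, 0.0) / np.maximum(fintro, eps)
    with np.errstate(divide="ignore"):
        logratio = np.where(ratio > 0, np.log(np.where(ratio > 0, ratio, 1.0)), np.nan)
    # zero-F_ST units carry information (definitely not RI): keep them on the
    # log scale at a floor one decade below the smallest positive ratio
    pos = ratio[np.isfinite(ratio) & (ratio > 0)]
    if pos.size:
        floor = np.log(pos.min()) - np.log(10.0)
        logratio = np.where(np.isfinite(ratio) & (ratio == 0), floor, logratio)
    return RatioTrack(
        values=ratio,
        log_values=logratio,
        fst=fst,
        fintro=fintro,
        scale=scale,
        positions=positions,
        windows=windows,
        eps=float(eps),
    )


def fit_hmm(
    track: RatioTrack | np.ndarray,
    *,
    n_states: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
    init_quantiles: tuple[float, ...] = (0.20, 0.60, 0.95),
    sticky: float = 0.5,
) -> tuple[RIHMMModel, np.ndarray]:
    """Baum-Welch fit of the Gaussian ratio HMM on one chromosome's track.

    Emissions are Gaussian on the log ratio; state means are initialised at
    the 20/60/95th percentiles and kept ordered by relabelling after the
    fit.  ``sticky`` adds a diagonal pseudocount of ``sticky * n_units`` to
    the transition M-step, favouring persistent states over a degenerate
    mixture reading of the track (states are genomic regimes, not mixture
    components).  Returns the model and the (n_units, n_states) posterior
    matrix (NaN rows for undefined units, which are skipped by the chain).
    """
    x_full = track.log_values if isinstance(track, RatioTrack) else np.asarray(track, float)
    ok = np.isfinite(x_full)
    x = x_full[ok]
    if x.size < 100:
        raise ValueError(f"need >= 100 defined units per chromosome, got {x.size}")
    means = np.quantile(x, init_quantiles[:n_states]).astype(float)
    spread = max(np.std(x) / n_states, 1e-3)
    sds = np.full(n_states, spread)
    trans = np.full((n_states, n_states), 0.02 / (n_states - 1))
    np.fill_diagonal(trans, 0.98)
    pi = np.full(n_states, 1.0 / n_states)
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        loge = gaussian_log_emissions(x, means, sds)
        gamma, xi, loglik = forward_backward(loge, trans, pi)
        occ = np.maximum(gamma.sum(axis=0), 1e-12)
        means = gamma.T @ x / occ
        sds = np.sqrt(np.maximum((gamma * (x[:, None] - means[None, :]) ** 2).sum(0) / occ, 1e-8))
        xi = xi + sticky * x.size * np.eye(n_states)
        trans = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
        pi = gamma[0]
        if loglik - prev < tol and n_iter > 1:
            converged = True
            break
        prev = loglik
    if not converged:
        logger.warning("RI HMM did not converge in %d iterations", max_iter)
    order = np.argsort(means)  # enforce low < intermediate < high
    means, sds, pi = means[order], sds[order], pi[order]
    trans = trans[np.ix_(order, order)]
    loge = gaussian_log_emissions(x, means, sds)
    gamma, _, loglik = forward_backward(loge, trans, pi)
    post = np.full((len(x_full), n_states), np.nan)
    post[ok] = gamma
    model = RIHMMModel(
        transition=trans, means=means, sds=sds, init=pi,
        loglik=loglik, n_iter=n_iter, converged=converged,
    )
    return model, post


def call_islands(
    track: RatioTrack,
    posteriors: np.ndarray,
    *,
    alpha: float = 0.001,
    method: str = "fdr_bh",
    chrom: str = "chr1",
) -> RIIslandSet:
    """Benjamini-Hochberg FDR across units, then merge retained high-state
    units into maximal island intervals.

    The per-unit P-value for "this unit is not in the high state" is
    1 - P(high | data); a unit is retained when its adjusted value falls
    below ``alpha``.  Adjacent retained units (consecutive windows, or
    consecutive SNPs) form one island.
    """
    ph = posteriors[:, HIGH]
    state = _argmax_or_missing(posteriors)
    p = np.clip(1.0 - ph, 0.0, 1.0)
    ok = np.isfinite(p)
    p_adj = np.full_like(p, np.nan)
    if ok.any():
        _, adj, _, _ = multipletests(p[ok], alpha=alpha, method=method)
        p_adj[ok] = adj
    retained = ok & (p_adj < alpha) & (state == HIGH)

    if track.scale == "window":
        spans = [(w.start, w.end) for w in track.windows]
    else:
        spans = [(int(x), int(x) + 1) for x in track.positions]
    islands: list[tuple[int, int]] = []
    run_start = None
    for i, r in enumerate(retained):
        if r and run_start is None:
            run_start = i
        if run_start is not None and (not r or i == len(retained) - 1):
            stop = i if not r else i + 1
            islands.append((spans[run_start][0], spans[stop - 1][1]))
            run_start = None
    table = pd.DataFrame(
        {
            "start": [s for s, _ in spans],
            "end": [e for _, e in spans],
            "state": state,
            "posterior_high": ph,
            "p": p,
            "p_adj": p_adj,
            "retained": retained,
        }
    )
    return RIIslandSet(table=table, islands=islands, alpha=alpha, scale=track.scale, chrom=chrom)


def _argmax_or_missing(posteriors: np.ndarray) -> np.ndarray:
    out = np.full(posteriors.shape[0], -1, dtype=int)
    ok = np.isfinite(posteriors).all(axis=1)
    if ok.any():
        out[ok] = np.argmax(posteriors[ok], axis=1)
    return out


def concordance(snp_islands: RIIslandSet, window_islands: RIIslandSet) -> dict[str, float]:
    """Cross-tabulate SNP-scale and window-scale island calls.

    Reports the fraction of SNP-scale retained units falling inside
    window-scale islands and the fraction of window-island bases containing
    at least one retained SNP unit.
    """
    from . import intervals as iv

    snp_pos = snp_islands.table.loc[snp_islands.table.retained, "start"].to_numpy()
    win = window_islands.islands
    frac_snp_in_win = (
        float(iv.covers(win, snp_pos).mean()) if len(snp_pos) and win else np.nan
    )
    covered = sum(
        1 for s, e in win if ((snp_pos >= s) & (snp_pos < e)).any()
    ) if len(snp_pos) else 0
    frac_win_with_snp = covered / len(win) if win else np.nan
    return {
        "snp_units_in_window_islands": frac_snp_in_win,
        "window_islands_with_snp_support": frac_win_with_snp,
    }
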