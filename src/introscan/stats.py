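"""Per-window divergence and introgression statistics.

Implements the 50-kb window scan battery: absolute divergence d_XY, Weir &
Cockerham F_ST, Patterson's D with the f_D admixture-proportion estimator,
the RND_min statistic (minimum donor-recipient haplotype distance normalised
by outgroup divergence), topology weighting of per-window neighbor-joining
trees by quartet sampling, and Spearman correlation between genome-wide
tracks.

Distances are raw per-site mismatch proportions without multiple-hit
correction: the divergences involved (at most a few percent) are far from
saturation.  d_XY and RND_min denominate by the window span in bp by
default, which slightly underestimates divergence when inaccessible sites
were filtered out; pass ``denominator="sites"`` to use the SNP count
instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .panel import GenomicWindow, HaplotypePanel, window_site_slice

__all__ = [
    "dxy",
    "weir_cockerham_fst",
    "site_abba_baba",
    "abba_baba",
    "rnd_min",
    "topology_weights",
    "correlate_tracks",
]


def _window_denoms(windows, n_sites_per_window, denominator):
    if denominator == "span":
        return np.array([w.span for w in windows], dtype=float)
    if denominator == "sites":
        return np.asarray(n_sites_per_window, dtype=float)
    raise ValueError("denominator must be 'span' or 'sites'")


def dxy(
    panel: HaplotypePanel,
    pop_a: str,
    pop_b: str,
    windows: list[GenomicWindow],
    *,
    denominator: str = "span",
) -> np.ndarray:
    """Mean pairwise divergence between two populations per window.

    Equals the average over all cross-population haplotype pairs of their
    per-bp mismatch rate; windows without sites get 0 under the span
    denominator and NaN under the site-count denominator.
    """
    fa = panel.derived_freq(pop_a)
    fb = panel.derived_freq(pop_b)
    per_site = fa + fb - 2.0 * fa * fb  # mean cross-pair mismatch probability
    out = np.empty(len(windows))
    counts = np.empty(len(windows))
    for i, w in enumerate(windows):
        sl = window_site_slice(panel.positions, w)
        out[i] = per_site[sl].sum()
        counts[i] = sl.stop - sl.start
    denom = _window_denoms(windows, counts, denominator)
    with np.errstate(invalid="ignore", divide="ignore"):
        return out / denom


def weir_cockerham_fst(
    panel: HaplotypePanel,
    pop_a: str,
    pop_b: str,
    windows: list[GenomicWindow] | None = None,
    *,
    clamp_windows: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Weir & Cockerham (1984) F_ST from haplotype (allele-count) data.

    Per-SNP estimates use the two-level ANOVA variance components for
    haploid samples; negative per-SNP values are retained.  Window values
    are the ratio of summed numerator over summed denominator components
    ("ratio of averages"), optionally clamped at 0.  Monomorphic windows are
    NaN.

    Returns ``(per_snp, per_window)``; ``per_window`` is None when no
    windows are given.
    """
    ra = panel.haps(pop_a)
    rb = panel.haps(pop_b)
    n1, n2 = float(len(ra)), float(len(rb))
    if n1 < 2 or n2 < 2:
        raise ValueError("both populations need at least 2 haplotypes")
    p1 = panel.alleles[ra].mean(axis=0)
    p2 = panel.alleles[rb].mean(axis=0)
    n_tot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n_tot
    # r = 2 populations
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2.0)
    n_c = n_tot - (n1**2 + n2**2) / n_tot
    num = msp - msg
    den = msp + (n_c - 1.0) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if windows is None:
        return per_snp, None
    per_window = np.empty(len(windows))
    for i, w in enumerate(windows):
        sl = window_site_slice(panel.positions, w)
        d = den[sl].sum()
        if d <= 0:
            per_window[i] = np.nan  # monomorphic window: estimator undefined
        else:
            v = num[sl].sum() / d
            per_window[i] = max(v, 0.0) if clamp_windows else v
    return per_snp, per_window


def site_abba_baba(f1, f2, f3, f4) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ABBA and BABA weights from derived-allele frequencies."""
    f1, f2, f3, f4 = (np.asarray(f, dtype=float) for f in (f1, f2, f3, f4))
    abba = (1 - f1) * f2 * f3 * (1 - f4)
    baba = f1 * (1 - f2) * f3 * (1 - f4)
    return abba, baba


def abba_baba(
    panel: HaplotypePanel,
    windows: list[GenomicWindow],
    *,
    p1: str = "P1",
    p2: str = "P2",
    p3: str = "P3",
    outgroup: str = "O",
) -> pd.DataFrame:
    """Windowed ABBA-BABA test: Patterson's D and the f_D estimator.

    D measures the imbalance between ABBA genealogies (P2 sharing derived
    alleles with the donor P3) and BABA genealogies (P1 sharing with P3).
    f_D normalises the excess S = sum(ABBA) - sum(BABA) by its value when
    the donor population is substituted for the recipient, choosing site-wise
    as donor the population (P2 or P3) with the higher derived frequency;
    it estimates the admixture proportion.  f_D is reported only where D is
    positive for the tested direction (a negative excess has no
    admixture-proportion reading); windows with sum(ABBA) + sum(BABA) = 0
    have undefined D.
    """
    if not panel.polarized:
        raise ValueError("abba_baba requires an outgroup-polarized panel")
    f1 = panel.derived_freq(p1)
    f2 = panel.derived_freq(p2)
    f3 = panel.derived_freq(p3)
    f4 = panel.derived_freq(outgroup)
    abba, baba = site_abba_baba(f1, f2, f3, f4)
    fd_donor = np.maximum(f2, f3)
    abba_d, baba_d = site_abba_baba(f1, fd_donor, fd_donor, f4)
    rows = []
    for w in windows:
        sl = window_site_slice(panel.positions, w)
        sa, sb = abba[sl].sum(), baba[sl].sum()
        tot = sa + sb
        d = (sa - sb) / tot if tot > 0 else np.nan
        s_den = abba_d[sl].sum() - baba_d[sl].sum()
        if np.isnan(d) or d <= 0 or s_den <= 0:
            fd = np.nan
        else:
            fd = (sa - sb) / s_den
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": w.n_snps,
                "excluded": w.excluded,
                "abba_sum": sa,
                "baba_sum": sb,
                "D": d,
                "fD": fd,
            }
        )
    return pd.DataFrame(rows)


def _pair_mismatch_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(len(a) x len(b)) mismatch counts between two haplotype blocks."""
    a = a.astype(np.int32)
    b = b.astype(np.int32)
    # |x - y| summed = x(1-y) + y(1-x) summed, via two matrix products
    return a @ (1 - b).T + (1 - a) @ b.T


def rnd_min(
    panel: HaplotypePanel,
    donor_pop: str,
    recipient_pop: str,
    outgroup_pop: str,
    windows: list[GenomicWindow],
    *,
    denominator: str = "span",
) -> pd.DataFrame:
    """RND_min per window: min donor-recipient distance over outgroup divergence.

    d_min is the minimum per-bp distance over all donor x recipient
    haplotype pairs; d_out averages the divergence of the outgroup to the
    donor and to the recipient population.  Low RND_min flags introgressed
    haplotypes while staying robust to mutation-rate variation.  Windows
    with d_out = 0 are undefined (NaN).
    """
    rd = panel.haps(donor_pop)
    rr = panel.haps(recipient_pop)
    ro = panel.haps(outgroup_pop)
    rows = []
    for w in windows:
        sl = window_site_slice(panel.positions, w)
        ad = panel.alleles[rd, sl]
        ar = panel.alleles[rr, sl]
        ao = panel.alleles[ro, sl]
        denom = float(w.span) if denominator == "span" else float(sl.stop - sl.start)
        if denom == 0:
            rows.append((w.start, w.end, np.nan, np.nan, np.nan))
            continue
        d_min = _pair_mismatch_counts(ad, ar).min() / denom
        d_od = _pair_mismatch_counts(ao, ad).mean() / denom
        d_or = _pair_mismatch_counts(ao, ar).mean() / denom
        d_out = 0.5 * (d_od + d_or)
        rnd = d_min / d_out if d_out > 0 else np.nan
        rows.append((w.start, w.end, d_min, d_out, rnd))
    return pd.DataFrame(rows, columns=["start", "end", "d_min", "d_out", "rnd_min"])


def _quartet_topology(dm: np.ndarray, o: int, h3: int, h2: int, h1: int) -> np.ndarray:
    """Weights (species, P3P2, P3P1) of one quartet by the four-point rule."""
    s_sp = dm[h1, h2] + dm[h3, o]  # split {P1,P2} | {P3,O}
    s_32 = dm[h3, h2] + dm[h1, o]  # split {P3,P2} | {P1,O}
    s_31 = dm[h3, h1] + dm[h2, o]  # split {P3,P1} | {P2,O}
    sums = np.array([s_sp, s_32, s_31])
    best = np.isclose(sums, sums.min())
    return best / best.sum()  # ties share the weight equally


def topology_weights(
    panel: HaplotypePanel,
    windows: list[GenomicWindow],
    *,
    taxa: tuple[str, str, str, str] = ("O", "P3", "P2", "P1"),
    n_quartets: int = 500,
    enum_cap: int = 2000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Topology weighting by subtree sampling of per-window NJ trees.

    For each window a neighbor-joining tree is built from raw pairwise
    haplotype distances; every sampled quartet (one haplotype per taxon,
    rooted on the outgroup) contributes its induced topology, read off the
    tree's patristic distances by the four-point condition.  All quartets
    are enumerated when their number is at most ``enum_cap``, otherwise
    ``n_quartets`` are drawn uniformly.  Returns the ``(n_windows, 3)``
    weights — species tree, donor-with-P2, donor-with-P1 — and a degenerate
    flag for windows with no informative variation (uniform weights).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    rng = np.random.default_rng(seed)
    o_pop, p3_pop, p2_pop, p1_pop = taxa
    groups = [panel.haps(p) for p in taxa]
    labels = [f"t{i}" for i in range(sum(len(g) for g in groups))]
    rows = np.concatenate(groups)
    offsets = np.cumsum([0] + [len(g) for g in groups])
    weights = np.full((len(windows), 3), 1.0 / 3.0)
    degenerate = np.zeros(len(windows), dtype=bool)

    n_combo = int(np.prod([len(g) for g in groups]))
    for wi, w in enumerate(windows):
        sl = window_site_slice(panel.positions, w)
        block = panel.alleles[rows, sl]
        n_sites = sl.stop - sl.start
        mism = _pair_mismatch_counts(block, block).astype(float)
        if n_sites == 0 or mism.max() == 0:
            degenerate[wi] = True
            continue
        dm = DistanceMatrix(mism / n_sites, ids=labels)
        tree = nj(dm)
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0  # NJ can yield negative edges; clamp
        tt = tree.tip_tip_distances(endpoints=labels)
        pat = np.asarray(tt.data)
        order = {t: i for i, t in enumerate(tt.ids)}
        remap = np.array([order[t] for t in labels])
        pat = pat[np.ix_(remap, remap)]

        if n_combo <= enum_cap:
            quartets = itertools.product(
                range(offsets[0], offsets[1]),
                range(offsets[1], offsets[2]),
                range(offsets[2], offsets[3]),
                range(offsets[3], offsets[4]),
            )
            total = n_combo
        else:
            quartets = (
                (
                    int(rng.integers(offsets[0], offsets[1])),
                    int(rng.integers(offsets[1], offsets[2])),
                    int(rng.integers(offsets[2], offsets[3])),
                    int(rng.integers(offsets[3], offsets[4])),
                )
                for _ in range(n_quartets)
            )
            total = n_quartets
        acc = np.zeros(3)
        for o, h3, h2, h1 in quartets:
            acc += _quartet_topology(pat, o, h3, h2, h1)
        weights[wi] = acc / total
    return weights, degenerate


def correlate_tracks(track_a, track_b) -> tuple[float, float]:
    """Spearman rank correlation between two aligned per-window tracks.

    Uses pairwise-complete windows; fewer than 3 complete pairs is an error.
    """
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must be aligned on the same windows")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 pairwise-complete windows")
    rho, p = spearmanr(a[ok], b[ok])
    return float(rho), float(p)
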