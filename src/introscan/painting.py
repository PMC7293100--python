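"""Two-panel haplotype-copying local ancestry and F_intro.

Each focal recipient haplotype is modelled as an imperfect mosaic copy of
the haplotypes in two reference panels of pure lineages (Atlantic-like panel
A and Mediterranean-like panel B), in the style of Li & Stephens: the hidden
state is the panel member currently being copied, switches occur at a rate
proportional to the recombination distance between adjacent sites, and
emissions allow a small mismatch probability.  The per-site probability of
ancestry A is the total posterior copying mass on panel-A members.  This is
a deliberately simple stand-in for Chromopainter with a uniform within-panel
prior: the analyses downstream consume the ancestry probability profile, not
the painter's internals.

Tracts of the minority ancestry are extracted from the profile by a
threshold rule (P > 0.5), with boundaries at the midpoint between flanking
sites of opposite call, short gaps merged, and poorly supported tracts
dropped; combining haplotypes gives F_intro, the fraction of haplotypes
whose introgressed tract covers a position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import intervals as iv
from .hmm import ls_posterior
from .panel import GenomicWindow, HaplotypePanel

logger = logging.getLogger("introscan")

__all__ = [
    "CopyingModel",
    "AncestryTractSet",
    "paint",
    "paint_population",
    "extract_tracts",
    "f_intro",
    "f_intro_at",
]


@dataclass
class CopyingModel:
    """Reference panels plus switch/mismatch parameters of the copying HMM.

    ``switch_rate`` is per bp; the default scales the recombination rate by
    ``switch_scale`` (an effective-population-size-times-panel-size
    constant), giving expected copy-segment lengths of ``1/switch_rate``.
    """

    panel_a: np.ndarray  # (K_A, n_sites)
    panel_b: np.ndarray  # (K_B, n_sites)
    positions: np.ndarray
    switch_rate: float
    mismatch: float = 1e-3

    def __post_init__(self) -> None:
        if self.panel_a.shape[0] == 0 or self.panel_b.shape[0] == 0:
            raise ValueError("both reference panels must be non-empty")
        if not 0 < self.mismatch < 1 or not self.switch_rate > 0:
            raise ValueError("switch_rate and mismatch must be in (0, 1)")

    @classmethod
    def from_panel(
        cls,
        panel: HaplotypePanel,
        pop_a: str,
        pop_b: str,
        *,
        r: float = 1e-8,
        switch_scale: float = 2000.0,
        mismatch: float = 1e-3,
    ) -> "CopyingModel":
        return cls(
            panel_a=panel.alleles[panel.haps(pop_a)],
            panel_b=panel.alleles[panel.haps(pop_b)],
            positions=panel.positions,
            switch_rate=r * switch_scale,
            mismatch=mismatch,
        )


@dataclass
class AncestryTractSet:
    """Per-haplotype introgressed tracts plus their mean posterior support."""

    tracts: dict[str, list[tuple[int, int]]]
    mean_posterior: dict[str, list[float]]
    ancestry: str
    chrom: str
    chrom_length: int


def paint(focal: np.ndarray, model: CopyingModel) -> np.ndarray:
    """Per-site posterior probability that the focal haplotype copies from
    panel A.  The focal haplotype must not be a member of either panel."""
    focal = np.asarray(focal, dtype=np.uint8)
    refs = np.vstack([model.panel_a, model.panel_b])
    if focal.shape[0] != refs.shape[1]:
        raise ValueError("focal haplotype and panels must share the site grid")
    mismatch = (refs != focal[None, :]).T.astype(np.uint8)  # (S, K)
    dists = np.diff(model.positions).astype(float)
    switch = 1.0 - np.exp(-model.switch_rate * dists)
    gamma = ls_posterior(mismatch, switch, model.mismatch)
    return gamma[:, : model.panel_a.shape[0]].sum(axis=1)


def paint_population(
    panel: HaplotypePanel, focal_pop: str, model: CopyingModel
) -> tuple[list[str], np.ndarray]:
    """Paint every haplotype of ``focal_pop``; returns ids and (n_hap, S) P(A)."""
    rows = panel.haps(focal_pop)
    out = np.empty((len(rows), panel.n_sites))
    for i, row in enumerate(rows):
        out[i] = paint(panel.alleles[row], model)
    return [panel.hap_ids[r] for r in rows], out


def extract_tracts(
    positions: np.ndarray,
    p_target: np.ndarray,
    *,
    chrom_length: int,
    chrom: str = "chr1",
    hap_ids: list[str] | None = None,
    ancestry: str = "A",
    threshold: float = 0.5,
    merge_bp: int = 1000,
    min_sites: int = 3,
) -> AncestryTractSet:
    """Group sites with P(target ancestry) > threshold into tracts.

    Boundaries fall at the midpoint between the outermost supporting site
    and the nearest flanking site of opposite call (extended to the
    chromosome edge when a run is terminal); gaps shorter than ``merge_bp``
    are merged; tracts supported by fewer than ``min_sites`` sites are
    dropped.
    """
    p = np.atleast_2d(np.asarray(p_target, dtype=float))
    if p.shape[1] != len(positions):
        raise ValueError("posterior and positions must be aligned")
    if p.shape[1] < 2:
        raise ValueError("need posteriors at >= 2 sites")
    if hap_ids is None:
        hap_ids = [f"hap{i}" for i in range(p.shape[0])]
    logger.info(
        "extract_tracts: threshold=%g merge_bp=%d min_sites=%d",
        threshold, merge_bp, min_sites,
    )
    tracts: dict[str, list[tuple[int, int]]] = {}
    support: dict[str, list[float]] = {}
    for i, hap in enumerate(hap_ids):
        call = p[i] > threshold
        edges = np.diff(np.concatenate([[0], call.view(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1) - 1  # inclusive site indices
        raw = []
        for s, e in zip(starts, ends):
            lo = 0 if s == 0 else (positions[s - 1] + positions[s]) // 2 + 1
            hi = (
                chrom_length
                if e == len(positions) - 1
                else (positions[e] + positions[e + 1]) // 2 + 1
            )
            raw.append((int(lo), int(hi), int(e - s + 1), float(p[i, s : e + 1].mean())))
        merged: list[list] = []
        for lo, hi, n, mp in raw:
            if merged and lo - merged[-1][1] < merge_bp:
                w_old = merged[-1][2]
                merged[-1][1] = hi
                merged[-1][2] += n
                merged[-1][3] = (merged[-1][3] * w_old + mp * n) / (w_old + n)
            else:
                merged.append([lo, hi, n, mp])
        kept = [(lo, hi, mp) for lo, hi, n, mp in merged if n >= min_sites]
        tracts[hap] = [(lo, hi) for lo, hi, _ in kept]
        support[hap] = [mp for _, _, mp in kept]
    return AncestryTractSet(
        tracts=tracts,
        mean_posterior=support,
        ancestry=ancestry,
        chrom=chrom,
        chrom_length=chrom_length,
    )


def f_intro(
    tracts: AncestryTractSet | dict, windows: list[GenomicWindow], n_haplotypes: int | None = None
) -> np.ndarray:
    """Per-window F_intro: mean fraction of haplotypes covered by a tract.

    The window value is the exact base-pair average of the per-position
    haplotype coverage fraction.
    """
    tr = tracts.tracts if isinstance(tracts, AncestryTractSet) else tracts
    n = n_haplotypes or len(tr)
    if n == 0:
        raise ValueError("need tracts from at least one haplotype")
    out = np.zeros(len(windows))
    for i, w in enumerate(windows):
        covered = sum(iv.coverage_in_window(t, w.start, w.end) for t in tr.values())
        out[i] = covered / (n * w.span)
    return out


def f_intro_at(
    tracts: AncestryTractSet | dict, positions: np.ndarray, n_haplotypes: int | None = None
) -> np.ndarray:
    """F_intro evaluated at individual positions (SNP scale)."""
    tr = tracts.tracts if isinstance(tracts, AncestryTractSet) else tracts
    n = n_haplotypes or len(tr)
    if n == 0:
        raise ValueError("need tracts from at least one haplotype")
    out = np.zeros(len(positions), dtype=float)
    for t in tr.values():
        out += iv.covers(t, positions)
    return out / n
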