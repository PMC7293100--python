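"""Conditioned (joint) site frequency spectra of donor-derived alleles.

Restricting to sites where the outgroup carries the ancestral allele and the
donor species the derived allele (ABBA-BABA-informative sites) isolates the
variants most likely to trace ancient donor ancestry.  Tallying the derived
counts of these alleles in the two recipient lineages — one-dimensional CSFS
per lineage, two-dimensional CJSFS jointly — separately for sites inside and
outside RI islands exposes the signature of admixture-derived isolation:
donor alleles fixed or nearly fixed in one lineage while rare in the other.
Counts are haplotype counts (axes run 0..n_haplotypes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import intervals as iv
from .panel import HaplotypePanel

__all__ = [
    "ConditionedSFS",
    "conditioning_mask",
    "build_csfs_cjsfs",
    "corner_asymmetry",
]


@dataclass
class ConditionedSFS:
    """CSFS vectors for each recipient lineage and their joint CJSFS matrix.

    ``cjsfs[i, j]`` counts sites with ``i`` derived copies in P1 and ``j``
    in P2; row/column sums reproduce the one-dimensional spectra.
    """

    csfs_p1: np.ndarray
    csfs_p2: np.ndarray
    cjsfs: np.ndarray
    site_class: str
    n_sites: int


def conditioning_mask(
    panel: HaplotypePanel,
    *,
    donor: str = "P3",
    outgroup: str = "O",
    donor_freq_threshold: float = 0.0,
) -> np.ndarray:
    """Sites where the outgroup is fixed ancestral and the donor carries the
    derived allele (frequency > ``donor_freq_threshold``; the default
    "present" rule suits a single sequenced donor individual)."""
    if not panel.polarized:
        raise ValueError("conditioning requires an outgroup-polarized panel")
    f_out = panel.derived_freq(outgroup)
    f_donor = panel.derived_freq(donor)
    return (f_out == 0.0) & (f_donor > donor_freq_threshold)


def build_csfs_cjsfs(
    panel: HaplotypePanel,
    mask: np.ndarray,
    ri_intervals,
    *,
    p1: str = "P1",
    p2: str = "P2",
) -> dict[str, ConditionedSFS]:
    """Tally conditioned spectra separately for RI and non-RI sites.

    ``ri_intervals`` is any interval list (e.g. ``RIIslandSet.islands``).
    Returns ``{"RI": ..., "non-RI": ...}``.
    """
    mask = np.asarray(mask, dtype=bool)
    rows1 = panel.haps(p1)
    rows2 = panel.haps(p2)
    n1, n2 = len(rows1), len(rows2)
    c1 = panel.alleles[rows1].sum(axis=0).astype(np.int64)
    c2 = panel.alleles[rows2].sum(axis=0).astype(np.int64)
    in_ri = iv.covers(list(ri_intervals), panel.positions)
    out = {}
    for label, cls_mask in [("RI", mask & in_ri), ("non-RI", mask & ~in_ri)]:
        k1 = c1[cls_mask]
        k2 = c2[cls_mask]
        cj = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
        np.add.at(cj, (k1, k2), 1)
        out[label] = ConditionedSFS(
            csfs_p1=cj.sum(axis=1),
            csfs_p2=cj.sum(axis=0),
            cjsfs=cj,
            site_class=label,
            n_sites=int(cls_mask.sum()),
        )
    return out


def corner_asymmetry(sfs: ConditionedSFS, frac: float = 0.25) -> float:
    """Mass near (P1 rare, P2 fixed) relative to the mirrored corner.

    ``frac`` sets the corner size: "rare" means at most ``frac`` of the
    haplotypes derived, "fixed" at least ``1 - frac``.  A ratio > 1 means
    donor alleles preferentially reach high frequency in P2 while staying
    rare in P1 — the RI-island signature.  A pseudocount of 1 in the
    denominator keeps an empty mirrored corner finite.
    """
    n1 = sfs.cjsfs.shape[0] - 1
    n2 = sfs.cjsfs.shape[1] - 1
    lo1 = int(np.floor(frac * n1))
    hi2 = int(np.ceil((1 - frac) * n2))
    lo2 = int(np.floor(frac * n2))
    hi1 = int(np.ceil((1 - frac) * n1))
    p2_fixed_p1_rare = sfs.cjsfs[: lo1 + 1, hi2:].sum()
    p1_fixed_p2_rare = sfs.cjsfs[hi1:, : lo2 + 1].sum()
    return float(p2_fixed_p1_rare) / float(max(p1_fixed_p2_rare, 1))
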