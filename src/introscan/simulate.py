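"""Tract-level simulator for a four-taxon admixture scenario.

Generates phased haplotype panels for the species topology
``(((P1, P2), P3), O)`` — a Mediterranean-role recipient lineage P1, an
Atlantic-role recipient lineage P2, a donor species P3 and an outgroup O —
with

* an ancient admixture pulse P3 -> P2 (fraction ``a``, ``t_adm`` generations
  ago) laid down as an exponential mosaic of archaic tracts, and
* a recent secondary contact P2 -> P1 (fraction ``m``, ``t_sc`` generations
  ago) that copies Atlantic haplotype segments into Mediterranean genomes,

plus ground-truth tract coordinates for every haplotype.  The generative
model is deliberately the exact inverse of the tract-length dating law used
downstream: introgressed tract lengths are exponential with mean
``[(1-f) * r * (t-1)]**-1``, so parameter recovery is a sharp test.  It is a
tract-level model, not a coalescent: drift, ILS genealogy and demography are
only emulated (ILS by a low off-tract "leak" rate of donor-diagnostic
alleles).

Inside designated reproductive-isolation intervals (``ri_intervals``),
archaic ancestry in P2 is forced to high frequency ``q_ri`` and secondary-
contact introgression into P1 is suppressed, mimicking RI islands where
donor-derived haplotypes fixed in one lineage resist interlineage gene flow.

An optional pure-P1 reference group (``P1R``, no secondary contact) provides
the non-introgressed panel that local-ancestry painting requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import intervals as iv
from .panel import HaplotypePanel, write_bed, read_bed

__all__ = [
    "ScenarioParams",
    "TruthSet",
    "expected_tract_length",
    "simulate_panel",
    "export_truth",
    "load_truth",
]

POP_ORDER = ("O", "P3", "P2", "P1", "P1R")


def expected_tract_length(f: float, r: float, t: float) -> float:
    """Mean introgressed-tract length (bp) after a pulse: ``1/((1-f) r (t-1))``."""
    denom = (1.0 - f) * r * (t - 1.0)
    if denom <= 0:
        raise ValueError("need f < 1, r > 0 and t > 1 for a finite tract length")
    return 1.0 / denom


@dataclass
class ScenarioParams:
    """Study conditions for one simulated chromosome.

    Defaults describe a 10-Mb chromosome under the mid-divergence scenario
    used throughout the test-suite: an ancient pulse (a = 0.1) 5,000
    generations ago at a uniform recombination rate of 1e-8 M/bp, and a
    postglacial secondary contact (m = 0.31, 2,300 generations) matching the
    Atlantic ancestry fraction observed in western Mediterranean sea bass.
    Site densities are per-bp rates of the Poisson processes that place each
    variant class; ``leak`` is the off-tract carrier probability of
    donor-diagnostic alleles (ILS stand-in, 5% of the on-tract rate).
    """

    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    r: float = 1e-8
    n_hap: Mapping[str, int] = field(
        default_factory=lambda: {"O": 2, "P3": 2, "P2": 28, "P1": 28, "P1R": 16}
    )
    t_adm: float = 5_000.0
    a: float = 0.1
    t_sc: float = 2_300.0
    m: float = 0.31
    lam_shared: float = 0.002
    lam_p1: float = 0.001
    lam_p2: float = 0.001
    lam_p3: float = 0.002
    lam_out: float = 0.0005
    leak: float = 0.05
    ri_intervals: Sequence[tuple[int, int]] = ()
    q_ri: float = 0.95
    shared_freq_beta: tuple[float, float] = (0.5, 0.5)
    private_freq_beta: tuple[float, float] = (0.5, 3.0)
    fst_bg: float = 0.05
    n_founders: int = 6
    founder_segment_bp: int = 100_000

    def __post_init__(self) -> None:
        for name, val in [("a", self.a), ("m", self.m), ("q_ri", self.q_ri), ("leak", self.leak)]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for name in ("lam_shared", "lam_p1", "lam_p2", "lam_p3", "lam_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if not 0.0 <= self.fst_bg < 1.0:
            raise ValueError("fst_bg must be in [0, 1)")
        for s, e in self.ri_intervals:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"ri_interval ({s}, {e}) outside [0, {self.chrom_length})")
        if self.a > 0:
            mean = expected_tract_length(self.a, self.r, self.t_adm)
            if mean < 1.0:
                raise ValueError(
                    "mean archaic tract length < 1 bp for chosen (a, r, t_adm); "
                    "rescale t_adm or r"
                )
        if self.m > 0 and expected_tract_length(self.m, self.r, self.t_sc) < 1.0:
            raise ValueError(
                "mean secondary-contact tract length < 1 bp for chosen (m, r, t_sc); "
                "rescale t_sc or r"
            )


@dataclass
class TruthSet:
    """Ground-truth ancestry tracts for a simulated panel.

    ``archaic``: per-haplotype intervals of P3 (donor) ancestry — native
    archaic mosaics in P2, and in P1 the parts of secondary-contact tracts
    whose P2 donor was itself archaic.  ``atlantic``: per-P1-haplotype
    intervals of P2 ancestry acquired through secondary contact.
    """

    archaic: dict[str, list[tuple[int, int]]]
    atlantic: dict[str, list[tuple[int, int]]]
    ri_intervals: list[tuple[int, int]]
    chrom: str = "chr1"
    chrom_length: int = 0

    def tracts(self, kind: str) -> dict[str, list[tuple[int, int]]]:
        if kind not in {"archaic", "atlantic"}:
            raise KeyError(kind)
        return getattr(self, kind)

    def all_lengths(self, kind: str, restrict=None) -> np.ndarray:
        """Tract lengths (bp) pooled over haplotypes, optionally intersected
        with a restriction interval set."""
        lengths = []
        for tr in self.tracts(kind).values():
            if restrict is not None:
                tr = iv.intersect(tr, restrict)
            lengths.extend(e - s for s, e in tr)
        return np.asarray(lengths, dtype=float)

    def coverage_fraction(self, kind: str, hap_ids=None, region=None) -> float:
        """Mean fraction of the chromosome (or ``region``) covered by tracts."""
        tracts = self.tracts(kind)
        ids = list(tracts) if hap_ids is None else list(hap_ids)
        region = [(0, self.chrom_length)] if region is None else list(region)
        span = iv.total_length(region)
        if span == 0 or not ids:
            return 0.0
        tot = sum(iv.total_length(iv.intersect(tracts.get(h, []), region)) for h in ids)
        return tot / (span * len(ids))

    def coverage_at(self, kind: str, positions: np.ndarray) -> np.ndarray:
        """Per-position fraction of haplotypes covered by tracts of ``kind``."""
        tracts = self.tracts(kind)
        out = np.zeros(len(positions), dtype=float)
        for tr in tracts.values():
            out += iv.covers(tr, positions)
        return out / max(len(tracts), 1)


def _mosaic(rng: np.random.Generator, length: int, mean_on: float, frac: float):
    """Alternating exponential on/off mosaic with marginal on-fraction ``frac``."""
    if frac <= 0.0:
        return []
    if frac >= 1.0:
        return [(0, length)]
    mean_off = mean_on * (1.0 - frac) / frac
    on = rng.random() < frac
    pos = 0
    out = []
    while pos < length:
        seg = max(1, int(round(rng.exponential(mean_on if on else mean_off))))
        if on:
            out.append((pos, min(pos + seg, length)))
        pos += seg
        on = not on
    return out


def _dedupe_positions(pos: np.ndarray, order: np.ndarray, limit: int):
    """Sort positions and nudge collisions forward by 1 bp until unique."""
    srt = np.argsort(pos, kind="stable")
    p = pos[srt].astype(np.int64)
    for i in range(1, len(p)):
        if p[i] <= p[i - 1]:
            p[i] = p[i - 1] + 1
    keep = p < limit
    return p[keep], order[srt][keep]


def simulate_panel(params: ScenarioParams) -> tuple[HaplotypePanel, TruthSet]:
    """Simulate one chromosome; deterministic under ``params.seed``.

    Returns the phased panel (already polarized: 0 = ancestral by outgroup
    consensus, except at the ``lam_out`` outgroup-derived sites) and the
    :class:`TruthSet` of archaic and Atlantic tract coordinates.
    """
    rng = np.random.default_rng(params.seed)
    L = params.chrom_length
    ri = iv.merge_intervals(params.ri_intervals)

    pops = [p for p in POP_ORDER if params.n_hap.get(p, 0) > 0]
    hap_ids: list[str] = []
    individuals: list[str] = []
    populations: list[str] = []
    for p in pops:
        n = params.n_hap[p]
        if n % 2:
            raise ValueError(f"n_hap[{p}] must be even (diploid individuals), got {n}")
        for k in range(n):
            hap_ids.append(f"{p}_{k // 2:02d}_h{k % 2}")
            individuals.append(f"{p}_{k // 2:02d}")
            populations.append(p)
    row_of = {h: i for i, h in enumerate(hap_ids)}
    rows = {p: [i for i, q in enumerate(populations) if q == p] for p in pops}

    # --- ancestry mosaics -------------------------------------------------
    mean_arc = expected_tract_length(params.a, params.r, params.t_adm) if params.a > 0 else None
    archaic: dict[str, list[tuple[int, int]]] = {}
    for i in rows.get("P2", []):
        tr = _mosaic(rng, L, mean_arc, params.a) if mean_arc else []
        if ri:
            tr = iv.clip_out(tr, ri)
            forced = [itv for itv in ri if rng.random() < params.q_ri]
            tr = iv.merge_intervals(tr + forced)
        archaic[hap_ids[i]] = tr

    mean_sc = expected_tract_length(params.m, params.r, params.t_sc) if params.m > 0 else None
    atlantic: dict[str, list[tuple[int, int]]] = {}
    sc_donor: dict[str, list[int]] = {}
    p2_rows = rows.get("P2", [])
    for i in rows.get("P1", []):
        tr = _mosaic(rng, L, mean_sc, params.m) if mean_sc else []
        if ri:
            tr = iv.clip_out(tr, ri)
        atlantic[hap_ids[i]] = tr
        sc_donor[hap_ids[i]] = [int(rng.integers(len(p2_rows))) for _ in tr] if p2_rows else []

    # --- site placement ---------------------------------------------------
    def poisson_positions(lam: float) -> np.ndarray:
        n = rng.poisson(lam * L)
        return np.sort(rng.integers(0, L, size=n))

    classes = {
        "shared": poisson_positions(params.lam_shared),
        "p1": poisson_positions(params.lam_p1),
        "p2": poisson_positions(params.lam_p2),
        "diag": poisson_positions(params.lam_p3),
        "out": poisson_positions(params.lam_out),
    }
    cls_codes = {name: c for c, name in enumerate(classes)}
    pos_all = np.concatenate([classes[n] for n in classes])
    cls_all = np.concatenate(
        [np.full(len(classes[n]), cls_codes[n], dtype=np.int8) for n in classes]
    )
    positions, cls = _dedupe_positions(pos_all, cls_all, L)
    S = len(positions)
    n_rows = len(hap_ids)
    alleles = np.zeros((n_rows, S), dtype=np.uint8)

    is_shared = cls == cls_codes["shared"]
    is_p1 = cls == cls_codes["p1"]
    is_p2 = cls == cls_codes["p2"]
    is_diag = cls == cls_codes["diag"]
    is_out = cls == cls_codes["out"]

    if "O" in rows:
        alleles[np.ix_(rows["O"], np.flatnonzero(is_out))] = 1
    if "P3" in rows:
        alleles[np.ix_(rows["P3"], np.flatnonzero(is_diag))] = 1

    recip_rows = rows.get("P2", []) + rows.get("P1", []) + rows.get("P1R", [])
    med_rows = rows.get("P1", []) + rows.get("P1R", [])

    # Background (non-donor-diagnostic) variation is generated per lineage
    # from a small pool of founder haplotypes, and each haplotype is a
    # recombinant mosaic of its lineage's founders.  This produces the
    # within-lineage haplotype sharing (LD) that real phased panels have --
    # essential for haplotype-copying painting -- while keeping allele
    # frequencies at their drawn values in expectation.  Shared standing
    # variation drifts between the two recipient lineages (Balding-Nichols
    # with background F_ST ``fst_bg``), so background sites are weakly
    # lineage-informative; each lineage also carries private variants.
    shared_idx = np.flatnonzero(is_shared)
    p_anc = np.clip(rng.beta(*params.shared_freq_beta, size=len(shared_idx)), 0.01, 0.99)
    if params.fst_bg > 0:
        c = (1.0 - params.fst_bg) / params.fst_bg
        freq_shared_p1 = rng.beta(p_anc * c, (1.0 - p_anc) * c)
        freq_shared_p2 = rng.beta(p_anc * c, (1.0 - p_anc) * c)
    else:
        freq_shared_p1 = freq_shared_p2 = p_anc
    p1_idx = np.flatnonzero(is_p1)
    freq_p1_priv = rng.beta(*params.private_freq_beta, size=len(p1_idx))
    p2_idx = np.flatnonzero(is_p2)
    freq_p2_priv = rng.beta(*params.private_freq_beta, size=len(p2_idx))

    def founder_mosaic(lineage_rows, col_idx, col_freqs):
        nf = max(params.n_founders, 1)
        founders = rng.random((nf, len(col_idx))) < col_freqs[None, :]
        col_pos = positions[col_idx]
        for i in lineage_rows:
            n_bk = rng.poisson(L / params.founder_segment_bp)
            bounds = np.sort(rng.integers(0, L, size=n_bk))
            fids = rng.integers(0, nf, size=n_bk + 1)
            seg = np.searchsorted(bounds, col_pos, side="right")
            alleles[i, col_idx] = founders[fids[seg], np.arange(len(col_idx))]

    atl_cols = np.concatenate([shared_idx, p2_idx])
    atl_order = np.argsort(positions[atl_cols], kind="stable")
    atl_cols = atl_cols[atl_order]
    atl_freqs = np.concatenate([freq_shared_p2, freq_p2_priv])[atl_order]
    founder_mosaic(rows.get("P2", []), atl_cols, atl_freqs)

    med_cols = np.concatenate([shared_idx, p1_idx])
    med_order = np.argsort(positions[med_cols], kind="stable")
    med_cols = med_cols[med_order]
    med_freqs = np.concatenate([freq_shared_p1, freq_p1_priv])[med_order]
    founder_mosaic(med_rows, med_cols, med_freqs)

    diag_idx = np.flatnonzero(is_diag)
    diag_pos = positions[diag_idx]
    for i in recip_rows:
        hap = hap_ids[i]
        carried = rng.random(len(diag_idx)) < params.leak
        on_tract = iv.covers(archaic.get(hap, []), diag_pos)
        alleles[i, diag_idx] = carried | on_tract

    # --- secondary contact: copy donor P2 segments into P1 ----------------
    for hap, tracts in atlantic.items():
        i = row_of[hap]
        for (s, e), d in zip(tracts, sc_donor[hap]):
            lo, hi = np.searchsorted(positions, [s, e])
            alleles[i, lo:hi] = alleles[p2_rows[d], lo:hi]

    # truth archaic ancestry carried into P1 through secondary contact
    for hap, tracts in atlantic.items():
        got: list[tuple[int, int]] = []
        for (s, e), d in zip(tracts, sc_donor[hap]):
            got += iv.intersect([(s, e)], archaic[hap_ids[p2_rows[d]]])
        archaic[hap] = iv.merge_intervals(got)

    panel = HaplotypePanel(
        chrom=params.chrom,
        positions=positions,
        alleles=alleles,
        hap_ids=hap_ids,
        individuals=individuals,
        populations=np.array(populations, dtype=object),
        polarized=True,
        chrom_length=L,
    )
    truth = TruthSet(
        archaic=archaic,
        atlantic=atlantic,
        ri_intervals=ri,
        chrom=params.chrom,
        chrom_length=L,
    )
    return panel, truth


def export_truth(truth: TruthSet, prefix) -> dict[str, str]:
    """Write one BED per ancestry class (haplotype id in the name column)."""
    paths = {}
    for kind in ("archaic", "atlantic"):
        path = f"{prefix}.{kind}.bed"
        rows = [
            (truth.chrom, s, e, hap)
            for hap, tracts in sorted(truth.tracts(kind).items())
            for s, e in tracts
        ]
        write_bed(rows, path, header=f"truth {kind} tracts, name=haplotype id")
        paths[kind] = path
    path = f"{prefix}.ri.bed"
    write_bed(
        [(truth.chrom, s, e, "ri") for s, e in truth.ri_intervals],
        path,
        header="simulated reproductive-isolation intervals",
    )
    paths["ri"] = path
    return paths


def load_truth(prefix, chrom_length: int = 0) -> TruthSet:
    """Read back a truth set written by :func:`export_truth`."""
    out = {"archaic": {}, "atlantic": {}}
    chrom = "chr1"
    for kind in ("archaic", "atlantic"):
        df = read_bed(f"{prefix}.{kind}.bed")
        for _, row in df.iterrows():
            chrom = row["chrom"]
            out[kind].setdefault(row["name"], []).append((int(row["start"]), int(row["end"])))
    ri_df = read_bed(f"{prefix}.ri.bed")
    ri = [(int(r["start"]), int(r["end"])) for _, r in ri_df.iterrows()]
    return TruthSet(
        archaic=out["archaic"],
        atlantic=out["atlantic"],
        ri_intervals=ri,
        chrom=chrom,
        chrom_length=chrom_length,
    )
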