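"""Haplotype panels, genomic windows and standard-format I/O.

The in-memory substrate of every statistic in this package is the
:class:`HaplotypePanel`: a haplotypes x sites 0/1 allele matrix built from a
phased multi-sample VCF together with a sample->population map.  Internally
all coordinates are 0-based half-open; VCF output is 1-based and BED output
0-based, per each format's own convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("introscan")

__all__ = [
    "HaplotypePanel",
    "GenomicWindow",
    "RecombinationMap",
    "load_panel",
    "write_panel",
    "read_popmap",
    "read_recomb_map",
    "polarize",
    "make_windows",
    "window_site_slice",
    "read_bed",
    "write_bed",
]


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix with positions and population labels.

    Attributes
    ----------
    chrom
        Chromosome / contig identifier.
    positions
        Strictly increasing site coordinates in bp (0-based).
    alleles
        ``(n_haplotypes, n_sites)`` uint8 matrix.  ``1`` is the derived
        allele once :func:`polarize` has been applied, otherwise the ALT
        allele of the source VCF.
    hap_ids
        One identifier per haplotype row (``<sample>_h0`` / ``<sample>_h1``).
    individuals
        Individual (sample) each haplotype belongs to.
    populations
        Population label of each haplotype.
    polarized
        Whether allele codes are ancestral/derived (outgroup-polarized).
    chrom_length
        Chromosome length in bp when known; defaults to last position + 1.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    hap_ids: list[str]
    individuals: list[str]
    populations: np.ndarray
    polarized: bool = False
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x site matrix")
        if self.alleles.shape != (len(self.hap_ids), len(self.positions)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.hap_ids)} haplotypes x {len(self.positions)} sites"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("allele codes must be 0/1")
        if self.chrom_length is None:
            self.chrom_length = int(self.positions[-1]) + 1 if len(self.positions) else 0

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def haps(self, *pops: str) -> np.ndarray:
        """Row indices of the haplotypes belonging to ``pops``."""
        mask = np.isin(self.populations, list(pops))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"no haplotypes for population(s) {pops!r}")
        return idx

    def derived_freq(self, pop: str) -> np.ndarray:
        """Per-site frequency of allele 1 within ``pop``."""
        rows = self.haps(pop)
        return self.alleles[rows].mean(axis=0)

    def subset_sites(self, mask: np.ndarray) -> "HaplotypePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(self, positions=self.positions[idx], alleles=self.alleles[:, idx])

    def subset_haps(self, rows: np.ndarray) -> "HaplotypePanel":
        rows = np.asarray(rows)
        return replace(
            self,
            alleles=self.alleles[rows],
            hap_ids=[self.hap_ids[i] for i in rows],
            individuals=[self.individuals[i] for i in rows],
            populations=self.populations[rows],
        )


@dataclass
class GenomicWindow:
    """A window of the nonoverlapping tiling, 0-based half-open."""

    chrom: str
    start: int
    end: int
    n_snps: int = 0
    excluded: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class RecombinationMap:
    """Per-chromosome recombination rates in Morgans per bp."""

    rates: Mapping[str, float] = field(default_factory=dict)
    default: float | None = None

    def __post_init__(self) -> None:
        for chrom, r in self.rates.items():
            if not r > 0:
                raise ValueError(f"recombination rate for {chrom} must be > 0, got {r}")
        if self.default is not None and not self.default > 0:
            raise ValueError("default recombination rate must be > 0")

    def rate(self, chrom: str) -> float:
        if chrom in self.rates:
            return self.rates[chrom]
        if self.default is not None:
            return self.default
        raise KeyError(f"no recombination rate for chromosome {chrom!r}")


def read_popmap(path) -> dict[str, str]:
    """Read a two-column sample/population TSV (optional header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"popmap {path} needs two tab-separated columns")
    first = df.iloc[0]
    if str(first[0]).lower() in {"sample", "individual", "id"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_recomb_map(path, default: float | None = None) -> RecombinationMap:
    """Read a chrom / rate (Morgans per bp) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if isinstance(df.iloc[0, 1], str):
        df = df.iloc[1:]
    rates = {str(c): float(r) for c, r in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return RecombinationMap(rates=rates, default=default)


def load_panel(
    vcf_path,
    popmap_path=None,
    *,
    popmap: Mapping[str, str] | None = None,
    region: str | None = None,
    on_unphased: str = "drop",
) -> HaplotypePanel:
    """Build a :class:`HaplotypePanel` from a phased diploid VCF.

    Only biallelic SNPs are used.  Sites with any missing genotype are
    dropped and counted; unphased genotypes are either dropped with the site
    (``on_unphased="drop"``, default) or raise an error naming the sample and
    site (``on_unphased="error"``).

    Parameters
    ----------
    vcf_path
        Path to a VCF (plain or bgzipped) with phased diploid GT.
    popmap_path, popmap
        Sample->population assignment, as a TSV path or an in-memory mapping.
        Every listed sample must be present in the VCF.
    region
        Optional ``chrom`` or ``chrom:start-end`` restriction (1-based, as in
        tabix conventions).
    """
    from cyvcf2 import VCF

    if popmap is None:
        if popmap_path is None:
            raise ValueError("either popmap_path or popmap is required")
        popmap = read_popmap(popmap_path)
    if on_unphased not in {"drop", "error"}:
        raise ValueError("on_unphased must be 'drop' or 'error'")

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    missing = [s for s in popmap if s not in vcf_samples]
    if missing:
        raise ValueError(f"popmap sample(s) absent from VCF: {missing}")
    samples = [s for s in vcf_samples if s in popmap]
    sample_col = {s: vcf_samples.index(s) for s in samples}

    want_chrom = None
    want_lo = want_hi = None
    if region is not None:
        if ":" in region:
            want_chrom, rng = region.split(":")
            lo, hi = rng.replace(",", "").split("-")
            want_lo, want_hi = int(lo) - 1, int(hi)  # to 0-based half-open
        else:
            want_chrom = region

    positions: list[int] = []
    columns: list[np.ndarray] = []
    chrom = None
    n_dropped_missing = 0
    n_dropped_unphased = 0
    n_dropped_nonsnp = 0
    for var in vcf:
        if want_chrom is not None and var.CHROM != want_chrom:
            continue
        pos0 = var.POS - 1
        if want_lo is not None and not (want_lo <= pos0 < want_hi):
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError(
                f"multiple chromosomes in input ({chrom}, {var.CHROM}); "
                "load per-chromosome panels with region="
            )
        if not var.is_snp or len(var.ALT) != 1:
            n_dropped_nonsnp += 1
            continue
        gts = var.genotypes  # list of [a0, a1, phased]
        col = np.empty(2 * len(samples), dtype=np.int16)
        ok = True
        for j, s in enumerate(samples):
            a0, a1, phased = gts[sample_col[s]][:3]
            if a0 < 0 or a1 < 0:
                n_dropped_missing += 1
                ok = False
                break
            if not phased and a0 != a1:
                if on_unphased == "error":
                    raise ValueError(
                        f"unphased heterozygote for sample {s} at "
                        f"{var.CHROM}:{var.POS}"
                    )
                n_dropped_unphased += 1
                ok = False
                break
            col[2 * j] = a0
            col[2 * j + 1] = a1
        if not ok:
            continue
        positions.append(pos0)
        columns.append(col.astype(np.uint8))

    if n_dropped_missing or n_dropped_unphased or n_dropped_nonsnp:
        logger.info(
            "load_panel: dropped %d sites with missing genotypes, %d unphased, "
            "%d non-biallelic-SNP records",
            n_dropped_missing,
            n_dropped_unphased,
            n_dropped_nonsnp,
        )
    alleles = (
        np.stack(columns, axis=1) if columns else np.zeros((2 * len(samples), 0), np.uint8)
    )
    hap_ids = [f"{s}_h{k}" for s in samples for k in (0, 1)]
    individuals = [s for s in samples for _ in (0, 1)]
    populations = np.array([popmap[s] for s in samples for _ in (0, 1)], dtype=object)
    return HaplotypePanel(
        chrom=chrom if chrom is not None else "NA",
        positions=np.array(positions, dtype=np.int64),
        alleles=alleles,
        hap_ids=hap_ids,
        individuals=individuals,
        populations=populations,
    )


def write_panel(panel: HaplotypePanel, path) -> None:
    """Write a panel as a phased VCF (0 -> REF ``A``, 1 -> ALT ``T``).

    Haplotype rows are paired per individual in their stored order, so
    ``load_panel(write_panel(p))`` reproduces the allele matrix exactly.
    """
    samples = list(dict.fromkeys(panel.individuals))
    sample_rows = {s: [] for s in samples}
    for i, s in enumerate(panel.individuals):
        sample_rows[s].append(i)
    for s, rows in sample_rows.items():
        if len(rows) != 2:
            raise ValueError(f"individual {s} has {len(rows)} haplotypes, need 2 for VCF")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={panel.chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, pos in enumerate(panel.positions):
            col = panel.alleles[:, j]
            gts = "\t".join(
                f"{col[sample_rows[s][0]]}|{col[sample_rows[s][1]]}" for s in samples
            )
            fh.write(f"{panel.chrom}\t{pos + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def polarize(
    panel: HaplotypePanel,
    outgroup: str,
    *,
    polymorphic_outgroup: str = "drop",
) -> tuple[HaplotypePanel, np.ndarray]:
    """Recode alleles so the outgroup-consensus allele is 0 (ancestral).

    Sites where the outgroup is exactly 50/50 polymorphic have no defined
    consensus; they are dropped under the default rule
    (``polymorphic_outgroup="drop"``).  ``"major"`` keeps non-tied
    polymorphic sites using the outgroup major allele (ties are still
    dropped, being undefined).

    Returns the polarized panel and the boolean mask of retained sites (in
    the input panel's coordinates).
    """
    if polymorphic_outgroup not in {"drop", "major"}:
        raise ValueError("polymorphic_outgroup must be 'drop' or 'major'")
    rows = panel.haps(outgroup)
    freq = panel.alleles[rows].mean(axis=0)
    tied = np.isclose(freq, 0.5)
    if polymorphic_outgroup == "drop":
        keep = (freq == 0.0) | (freq == 1.0)
    else:
        keep = ~tied
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("polarize: dropped %d sites with ambiguous outgroup state", n_dropped)
    flip = freq > 0.5
    alleles = panel.alleles.copy()
    alleles[:, flip] = 1 - alleles[:, flip]
    out = replace(panel, alleles=alleles[:, keep], positions=panel.positions[keep])
    out.polarized = True
    return out, keep


def make_windows(
    panel_or_positions,
    span: int = 50_000,
    min_snps: int = 500,
    *,
    chrom_length: int | None = None,
    chrom: str | None = None,
) -> list[GenomicWindow]:
    """Tile ``[0, chrom_length)`` with nonoverlapping windows of ``span`` bp.

    The terminal window may be shorter.  Windows with fewer than ``min_snps``
    sites are flagged ``excluded`` but retained in the returned list.
    """
    if span <= 0:
        raise ValueError("span must be > 0")
    if isinstance(panel_or_positions, HaplotypePanel):
        positions = panel_or_positions.positions
        chrom_length = chrom_length or panel_or_positions.chrom_length
        chrom = chrom or panel_or_positions.chrom
    else:
        positions = np.asarray(panel_or_positions, dtype=np.int64)
        if chrom_length is None:
            chrom_length = int(positions[-1]) + 1 if len(positions) else span
        chrom = chrom or "NA"
    windows = []
    for start in range(0, max(chrom_length, 1), span):
        end = min(start + span, chrom_length)
        lo, hi = np.searchsorted(positions, [start, end])
        n = int(hi - lo)
        windows.append(
            GenomicWindow(chrom=chrom, start=start, end=end, n_snps=n, excluded=n < min_snps)
        )
    return windows


def window_site_slice(positions: np.ndarray, window: GenomicWindow) -> slice:
    """Slice of ``positions`` falling inside ``window`` (0-based half-open)."""
    lo, hi = np.searchsorted(positions, [window.start, window.end])
    return slice(int(lo), int(hi))


def write_bed(intervals: Iterable[tuple], path, *, header: str | None = None) -> None:
    """Write ``(chrom, start, end[, name[, score]])`` tuples as BED."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file into a DataFrame with chrom/start/end[/name] columns."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:4])
    df.columns = names[: df.shape[1]]
    return df
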