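"""Simulate a two-event admixture history and scan it in 50-kb windows.

Builds a 4-Mb chromosome for the four-taxon system (((P1,P2),P3),O) with an
ancient donor pulse into P2 and a recent secondary contact into P1, writes
and re-reads the panel as a phased VCF, and computes the window statistics:
d_XY, Weir-Cockerham F_ST, Patterson's D with f_D, and RND_min.
"""

import tempfile
from pathlib import Path

import numpy as np

import introscan as I
from introscan.scenarios import ri_scenario

params = ri_scenario(seed=1, chrom_length=4_000_000, ri_intervals=[(1_500_000, 2_000_000)])
panel, truth = I.simulate_panel(params)
print(f"simulated {panel.n_haplotypes} haplotypes x {panel.n_sites} SNPs on 4 Mb")

# round-trip through a phased VCF, as a real dataset would arrive
with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "panel.vcf"
    I.write_panel(panel, vcf)
    popmap = dict(zip(panel.individuals, panel.populations))
    panel = I.load_panel(vcf, popmap=popmap)
    panel.polarized = True  # simulated alleles are already outgroup-polarized

windows = I.make_windows(panel, span=50_000, min_snps=100)
dxy = I.dxy(panel, "P1", "P2", windows)
_, fst = I.weir_cockerham_fst(panel, "P1", "P2", windows)
abba = I.abba_baba(panel, windows)  # D > 0 means P3 shares alleles with P2
rnd = I.rnd_min(panel, "P3", "P1", "O", windows)

print(f"{'window':>18} {'d_XY':>8} {'F_ST':>6} {'D':>6} {'f_D':>6} {'RND_min':>8}")
for i in range(0, len(windows), 8):
    w = windows[i]
    print(
        f"{w.start:>8}-{w.end:<9} {dxy[i]:>8.5f} {fst[i]:>6.3f} "
        f"{abba.D[i]:>6.2f} {abba.fD[i]:>6.2f} {rnd.rnd_min[i]:>8.3f}"
    )

in_ri = np.array([any(s <= w.start and w.end <= e for s, e in params.ri_intervals)
                  for w in windows])
print(
    f"\nmean F_ST inside RI interval: {np.nanmean(fst[in_ri]):.3f}, "
    f"outside: {np.nanmean(fst[~in_ri]):.3f}"
)
print(
    f"mean f_D inside RI interval: {np.nanmean(abba.fD[in_ri]):.3f} "
    f"(donor ancestry forced to {params.q_ri} in P2 there), "
    f"outside: {np.nanmean(abba.fD[~in_ri]):.3f} (background pulse a = {params.a})"
)
print(
    "RND_min to P1 rises inside the RI interval "
    f"({np.nanmean(rnd.rnd_min[in_ri]):.3f} vs {np.nanmean(rnd.rnd_min[~in_ri]):.3f}): "
    "the Mediterranean-role lineage locally resists donor introgression."
)
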