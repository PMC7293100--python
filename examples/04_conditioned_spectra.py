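"""Conditioned site frequency spectra of donor-derived alleles.

Restricts to sites where the outgroup is ancestral and the donor species
carries the derived allele, then tallies derived counts in the two
recipient lineages separately for sites inside and outside the planted RI
intervals.  The RI-island signature is an excess of donor alleles at high
frequency in P2 (Atlantic role) but rare in P1 (Mediterranean role).
"""

import numpy as np

import introscan as I
from introscan.scenarios import ri_scenario

params = ri_scenario(seed=1)
panel, truth = I.simulate_panel(params)

mask = I.conditioning_mask(panel)
print(f"{mask.sum()} of {panel.n_sites} sites are donor-derived / outgroup-ancestral")

spectra = I.build_csfs_cjsfs(panel, mask, truth.ri_intervals)
for label, sfs in spectra.items():
    n1 = len(sfs.csfs_p1) - 1
    n2 = len(sfs.csfs_p2) - 1
    p1_rare = sfs.csfs_p1[: n1 // 4 + 1].sum() / max(sfs.n_sites, 1)
    p2_fixed = sfs.csfs_p2[-(n2 // 4 + 1) :].sum() / max(sfs.n_sites, 1)
    print(
        f"\n{label} sites (n={sfs.n_sites}): "
        f"P1 rare (<=25% of haplotypes) at {p1_rare:.1%} of sites; "
        f"P2 near-fixed (>=75%) at {p2_fixed:.1%}"
    )
    print(f"  corner asymmetry (P2-fixed & P1-rare vs mirror): "
          f"{I.corner_asymmetry(sfs):.1f}")

print(
    "\nAn asymmetry far above 1 for RI sites but not elsewhere shows donor "
    "haplotypes locally driven toward fixation in the Atlantic lineage while "
    "excluded from the Mediterranean - the joint-spectrum signature of "
    "admixture-derived reproductive isolation."
)
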