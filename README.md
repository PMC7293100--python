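# introscan

Detecting, localizing and dating **ancient interspecies admixture** — and
delineating the **reproductive-isolation (RI) islands** it leaves behind —
from phased whole-genome haplotype panels.

The motivating system is a four-taxon design `(((P1, P2), P3), O)`: two
partially isolated lineages of a recipient species (a Mediterranean-role
lineage P1 and an Atlantic-role lineage P2, as in European sea bass
*Dicentrarchus labrax*), a parapatric donor species P3 (spotted sea bass
role), and an outgroup O used to polarize alleles. The package answers
three questions: *did* the donor species introgress into one recipient
lineage; *where* along the genome do those archaic tracts sit relative to
the RI islands between the recipient lineages; and *when* did the admixture
happen.

## What it computes

**Window scans** (`introscan.stats`), in nonoverlapping 50-kb windows:

- absolute divergence d_XY and Weir & Cockerham (1984) F_ST;
- Patterson's D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA) with
  ABBA = (1−p₁)p₂p₃(1−p₄), BABA = p₁(1−p₂)p₃(1−p₄), and the admixture
  proportion estimator f_D = S(P1,P2,P3,O)/S(P1,P_D,P_D,O) with the dynamic
  donor P_D chosen site-wise;
- RND_min = d_min/d_out, the minimum donor–recipient haplotype distance
  normalised by mean divergence to the outgroup (robust to mutation-rate
  variation, sensitive to rare introgression);
- topology weighting of per-window neighbor-joining trees by quartet
  sampling (species topology vs the two donor-grouping topologies);
- Spearman correlations between any two genome-wide tracks.

**Archaic-tract detection** (`introscan.archaic`): a reference-free 2-state
Poisson HMM on per-haplotype counts of variants private with respect to a
non-admixed population, in 1-kb bins; tracts are posterior > 0.8 runs, and
F_archaic is the per-position fraction of covered haplotypes.

**Local-ancestry painting** (`introscan.painting`): a Li & Stephens-type
haplotype-copying HMM against two pure reference panels; introgressed
tracts and F_intro follow from the per-site ancestry posterior.

**RI islands** (`introscan.ri`): a 3-state Gaussian HMM
(low / intermediate / high) on log(F_ST/F_intro), at SNP and 50-kb scale,
with Benjamini–Hochberg FDR control (α = 0.001) on 1 − P(high).

**Dating** (`introscan.dating`): two estimators of the time since a pulse —

- tract lengths: t = 1/((1−f)·r·L̄) + 1 from the mean introgressed-tract
  length L̄, admixture fraction f and recombination rate r (M/bp), with
  calibration against a reference event of known age;
- HMM switch rate: T = p/(2·r·L·a) from the ancestry-switch probability p
  per L-bp bin, plus a KDE-mode + bootstrap-CI summary across chromosomes.

**Conditioned spectra** (`introscan.csfs`): CSFS/CJSFS of donor-derived
alleles (outgroup ancestral, donor derived) split by RI membership.

**Synthetic data** (`introscan.simulate`): a tract-level generator whose
introgressed-tract law is the exact inverse of the dating formula
(exponential lengths with mean [(1−f)r(t−1)]⁻¹), with founder-mosaic
background haplotypes, lineage drift, donor-diagnostic and outgroup-derived
variant classes, forced-high-frequency RI intervals, and full ground truth.

## Worked example

Dating the donor pulse from tract lengths, with the admixture proportions,
recombination rates and mean tract lengths estimated for the sea bass
system (donor tracts f = 0.096, r = 3.693×10⁻⁸ M/bp, L̄ = 5,513 bp; the
postglacial secondary contact f = 0.341, r = 3.23×10⁻⁸ M/bp,
L̄ = 52,026 bp, independently dated to 2,300 generations ≈ 11,500 years):

```python
>>> import introscan as I
>>> t_pulse = I.tract_length_date(5_513, 0.096, 3.693e-8)
>>> t_contact = I.tract_length_date(52_026, 0.341, 3.23e-8)
>>> round(t_pulse), round(t_contact), round(t_pulse / t_contact, 2)
(5434, 904, 6.01)
>>> round(I.calibrate_years(t_pulse, t_contact, 11_500))
69130
```

The donor tracts are ~9.4× shorter than the secondary-contact tracts, so
the pulse is ~6× older than the contact — about 70,000 years, placing it in
the last glacial period.

The end-to-end pipeline on simulated data (see `examples/` for the full
scripts) prints, for the 10-Mb pulse scenario (a = 0.1, t = 5,000
generations):

```
fitted Poisson rates per kb: native 0.024, archaic 0.458 (ratio 19.4)
F_archaic (called): 0.079; posterior-mass F_archaic: 0.100; simulated a = 0.1
simulated admixture time: 5000 generations
  tract-length dating, truth tracts :    5118 generations
  tract-length dating, called tracts:    4545 generations
  transition-rate dating            :    4463 generations
```

and for the RI scenario, the three planted 500-kb islands are recovered
exactly (100% of planted bases, 0 false bases at FDR 0.001).

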