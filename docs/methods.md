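# Methods

## The inference problem

Two partially reproductively isolated lineages of a recipient species (P1,
Mediterranean role; P2, Atlantic role) diverged recently and re-connected
through secondary contact; a more divergent donor species (P3) may have
admixed with one of them much earlier. Given phased haplotypes for the four
taxa `(((P1,P2),P3),O)`, the pipeline (i) tests for and localizes donor
introgression, (ii) delineates the genomic islands that resist interlineage
gene flow, and (iii) dates the admixture events. All statistics run on a
`HaplotypePanel`: a haplotypes × sites 0/1 matrix, polarized so 0 is the
outgroup-consensus (ancestral) allele, with strictly increasing 0-based
positions and no missing entries (sites with missing or unphased genotypes
are dropped at load time and counted).

## Models and estimators

**Patterson's D and f_D.** Site pattern weights are computed from
derived-allele frequencies, ABBA = (1−p₁)p₂p₃(1−p₄) and
BABA = p₁(1−p₂)p₃(1−p₄), summed per window; D is their normalized
difference. f_D divides S = ΣABBA−ΣBABA by its value with the donor
substituted for the recipient, choosing the donor site-wise as whichever of
{P2, P3} has the higher derived frequency. f_D is reported only where D is
positive for the tested direction — a negative excess has no reading as an
admixture proportion. On realistic data the dynamic-donor denominator also
accumulates terms from sites where the donor frequency is zero but the
recipients differ, so f_D mildly underestimates the admixture fraction
(a few percent in our simulations); it remains an accurate tracker of
*where* donor ancestry is concentrated.

**F_ST.** Weir & Cockerham (1984) in its haploid (allele-count) ANOVA
form, treating haplotypes as the sampling unit. Per-SNP estimates keep
negative values; window estimates are the ratio of summed numerator to
summed denominator components (ratio of averages), clamped at 0 by default
(configurable). Monomorphic windows are undefined (NaN), not zero.

**RND_min.** The minimum donor×recipient per-bp distance in a window over
the mean outgroup divergence d_out (average of O↔donor and O↔recipient).
Distances are raw mismatch proportions without multiple-hit correction:
all divergences in scope are ≤ ~5%, far from saturation. d_XY and RND_min
denominate by window span by default (an accessible-site denominator is
available); since both numerator and denominator of RND_min share the
convention, the ratio is insensitive to it.

**Topology weighting.** Per window, a neighbor-joining tree (scikit-bio)
is built from raw pairwise haplotype distances; negative NJ branch lengths
are clamped to zero. Each quartet (one haplotype per taxon) contributes the
topology read off the tree's patristic distances by the four-point
condition; ties split their weight equally. All quartets are enumerated
when their count is ≤ `enum_cap` (default 2,000), otherwise quartets are
sampled uniformly with a seeded generator. Windows with no informative
variation get uniform weights and a degeneracy flag.

**Archaic-tract HMM.** For each focal haplotype, variants whose derived
allele is absent from every haplotype of the non-admixed comparison
population are counted in 1-kb bins. A 2-state HMM with Poisson emissions
(λ_native < λ_archaic) and free transitions is fitted per haplotype by
Baum–Welch (tolerance 1e-6 log-likelihood units, ≤ 500 iterations,
≥ 100 bins required); initialization sets λ_native to a tenth of the 25th
percentile of nonzero bin counts, λ_archaic = 10×λ_native, and
native→archaic probability 1e-3. Labels are ordered by rate after fitting;
fits where the rates collapse (within 1%) are flagged degenerate and
treated as no-calls. Tracts are maximal runs of bins with archaic posterior
> 0.8; F_archaic is the per-position fraction of haplotypes covered,
averaged in 50-kb windows. Population-level parameters are obtained by
averaging per-haplotype estimates. Both F_archaic and F_intro are
haplotype fractions (not individual fractions); with n diploid individuals
the two differ only by the within-individual correlation of ancestry, and
the haplotype version is the one the copying and Poisson models actually
estimate.

**Local-ancestry painting.** A Li & Stephens-type copying model: the
hidden state is the reference-panel haplotype currently copied, with a
uniform within-panel prior; between adjacent sites separated by d bp the
state is redrawn uniformly with probability 1 − exp(−ρd), with switch rate
ρ = r × `switch_scale` (default 2,000, an effective panel-scaled constant
giving ~50-kb copy segments at r = 1e-8); emissions mismatch with
probability 1e-3. P(ancestry A) is the posterior mass on panel-A members.
This is a deliberate simplification of Chromopainter-style painting — the
downstream analyses consume only the ancestry profile. Tract extraction:
sites with P(target ancestry) > 0.5 form runs; boundaries fall at the
midpoint between the outermost supporting site and the nearest
opposite-call site (chromosome edges extend the terminal runs); gaps
< `merge_bp` (default 1,000) merge; runs with < `min_sites` (default 3)
supporting sites are dropped. All three knobs are logged.

**RI islands.** The per-unit ratio F_ST/F_intro is regularised by flooring
F_intro at ε = 1/(2·n_haplotypes) (one haplotype below detectability) and
negative per-SNP F_ST at 0; zero ratios are kept on the log scale one
decade below the smallest positive value. A 3-state Gaussian HMM on the
log ratio (low = neutral, intermediate = linked selection, high = RI) is
fitted chromosome-by-chromosome with Baum–Welch; means initialise at the
20/60/95th percentiles and are kept ordered by relabelling. The transition
M-step adds a diagonal pseudocount of `sticky`×n_units (default 0.5):
states are genomic *regimes*, and without the persistence prior a
single-regime track is degenerately read as an i.i.d. mixture. Per-unit
P-values are 1 − P(high); Benjamini–Hochberg across all units; units with
adjusted p < 0.001 and maximum-posterior state "high" merge into islands.
A concordance report cross-tabulates SNP-scale and window-scale calls.

**Dating.** Tract-length dating inverts the neutral expectation
L̄ = [(1−f)·r·(t−1)]⁻¹; the mean length can be restricted to a supplied
interval set (e.g. RI windows only, where differential introgression makes
tract boundaries identifiable). Absolute ages come from the ratio to a
reference event of known age (no rounding applied). Transition-rate dating
inverts p ≈ T·2·r·L·a. The factor 2 makes this exact when p is the
*either-direction* ancestry-switch probability per L-bp window: a tract
mosaic with haploid admixture fraction a after T generations has junction
density 2a(1−a)rT ≈ 2arT per bp, while the one-directional native→archaic
rate is only arT. `ancestry_switch_probability` therefore returns the
stationary-weighted off-diagonal mass of the fitted chain
(π_nat·P(n→a) + π_arc·P(a→n)); feeding the formula the one-directional
rate instead would systematically halve T. The admixture fraction a is
taken as the mean archaic posterior mass (the chain's own estimate of
F_archaic), which is less threshold-sensitive than called-tract coverage.
The cross-chromosome summary is the mode of a Gaussian KDE (Silverman
bandwidth, 512-point grid) with a seeded bootstrap percentile CI
(default 10,000 resamples, 90% level — the level is a parameter).

**Conditioned spectra.** Sites where the outgroup is fixed ancestral and
the donor carries the derived allele (presence threshold, suiting a
single-individual donor sample; configurable for multi-sample donors) are
tallied by derived haplotype counts in P1 and P2, jointly (CJSFS) and
marginally (CSFS), separately for sites inside and outside RI islands. The
corner-asymmetry statistic compares mass at (P1 rare, P2 near-fixed)
against the mirrored corner; > 1 is the admixture-derived-RI signature.

## The synthetic-data generator

A tract-level generative model, not a coalescent. Its design goal is that
the dating formula is the exact inverse of the generative law, making
parameter recovery a sharp test:

- **Ancestry mosaics.** Each P2 haplotype alternates archaic/native
  segments with exponential lengths; archaic mean [(1−a)r(t_adm−1)]⁻¹ and
  marginal archaic fraction a. Each P1 haplotype receives Atlantic tracts
  the same way (fraction m, age t_sc), each tract copying a uniformly
  chosen P2 haplotype — so archaic ancestry reaches P1 only through
  secondary contact, and P1's truth archaic tracts are the intersections of
  its Atlantic tracts with the donor haplotype's archaic tracts. Inside RI
  intervals, each P2 haplotype is forced archaic with probability q_RI and
  secondary-contact tracts are clipped out of P1.
- **Variant classes**, Poisson-placed per bp and deduplicated with 1-bp
  jitter: donor-diagnostic sites (rate λ_p3; derived in P3, carried by a
  recipient haplotype iff on its archaic tract, else with leak probability
  0.05 — the ILS stand-in), shared standing variation (λ_shared, ancestral
  frequency Beta(0.5, 0.5) drifting between the recipient lineages by
  Balding–Nichols with background F_ST 0.05), lineage-private variants
  (λ_p1, λ_p2; frequencies Beta(0.5, 3)), and outgroup-derived sites
  (λ_out, for polarization exercises).
- **Haplotype structure.** Background (non-diagnostic) alleles are drawn
  once per lineage on a pool of 6 founder haplotypes, and every haplotype
  is a recombinant founder mosaic (segments ~100 kb). This supplies the
  within-lineage haplotype sharing real phased panels have; without it a
  copying painter has no haplotype signal to lock onto and panel-size noise
  dominates. The pure reference group P1R (16 haplotypes, no secondary
  contact) shares the P1 founder pool and plays the reconstituted pure
  Mediterranean reference panel.

Default conditions (10 Mb, r = 1e-8 M/bp; pulse a = 0.1 at t_adm = 5,000
generations; secondary contact m = 0.31 at t_sc = 2,300 generations;
28+28 recipient haplotypes, 2 donor, 2 outgroup) mirror the sea bass study
system: the ~31% Atlantic ancestry of western Mediterranean genomes, the
2,300-generation postglacial contact, and a donor pulse roughly twice as
old as its ~70-ky estimate would imply at these rates — chosen so that a
10-Mb chromosome holds >1,000 archaic tracts and recovery statistics have
small Monte-Carlo error. Three canonical scenarios (`introscan.scenarios`)
fix the study conditions: `pulse_scenario` (the pulse in isolation, with
background classes off so the private-variant channel runs at the
spec-level on/off rate ratio 1/leak = 20), `ri_scenario` (both events plus
three 500-kb RI intervals at q_RI = 0.95), and `null_scenario` (no
admixture, equal site densities, 50 windows).

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: coalescent genealogies and true ILS (the leak
is frequency-independent noise, not shared ancestral lineage sorting);
glacial bottlenecks and population-size change; selection against or for
introgressed tracts (the tract-length clock is exactly neutral here, so
simulated recovery cannot expose the selection bias that makes real
tract-length dates younger); gene conversion; variable recombination and
mutation rates along the chromosome; phasing and genotyping error. The
non-RI conditioned spectrum is one-sided (donor alleles only at low
frequency) rather than the bimodal spectrum real ILS+introgression
produces.

## Numerical choices

- Forward–backward runs in the linear domain with per-step scaling (numba
  kernels); posteriors match exhaustive path enumeration to <1e-9 on small
  instances, and Baum–Welch log-likelihoods are non-decreasing.
- Polarization: outgroup-consensus; exactly tied (50/50) outgroup sites are
  dropped under the default rule (a single-genome outgroup cannot tie;
  "major" mode keeps non-tied polymorphic sites). Polarization is an
  involution on outgroup-fixed sites.
- Coordinates are 0-based half-open internally; VCF output is 1-based, BED
  0-based. VCF is read through cyvcf2; only biallelic SNPs enter panels.
- Window tiling starts at 0, terminal window shorter; windows below the
  SNP minimum (default 500, scenario tests use ≥100) are flagged excluded,
  never silently removed.
- NJ/quartet ties split weight equally; quartet sampling is seeded.
- KDE-mode bootstrap and quartet sampling take explicit seeds; simulation
  is fully deterministic given `ScenarioParams.seed`.

## Problem sizes

The test-suite and the acceptance script run one 10-Mb chromosome per
scenario (~25–65 k SNPs, 28 focal haplotypes), which keeps the full
pipeline under a few minutes on one CPU while leaving >1,000 tracts for
dating and 200 windows for the island HMM; the estimators themselves are
linear in sites × haplotypes and run genome-scale inputs chromosome by
chromosome.

## Known limitations

- The two-panel painter assumes the reference panels are pure; panel
  contamination biases F_intro toward the contaminating ancestry. Panels
  are user-supplied (truth-pure in simulations).
- Transition-rate dating assumes the fitted switch probability reflects
  ancestry junctions only; at low signal-to-noise the HMM merges nearby
  tracts and the estimate drifts downward.
- The RI HMM's "intermediate" state is a catch-all for linked selection;
  with only two regimes present it absorbs little mass and the model
  effectively reduces to two states (harmless, but its occupancy should
  not be over-interpreted).
- f_D is undefined (NaN) in windows with a negative excess for the tested
  direction, and mildly conservative on drifted backgrounds (above).
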