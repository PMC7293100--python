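"""Canonical simulation scenarios used by the examples and the test-suite.

Three study conditions cover the pipeline's claims:

* :func:`pulse_scenario` — the ancient pulse in isolation (a = 0.1, 5,000
  generations, r = 1e-8 M/bp on 10 Mb), with background lineage variation
  switched off so the private-variant channel runs at the on/off-tract rate
  ratio 1/leak = 20.  Used for archaic-tract detection accuracy and for
  parameter (admixture-time) recovery.
* :func:`ri_scenario` — the full two-event history: the pulse plus the
  postglacial secondary contact (m = 0.31, 2,300 generations), with three
  500-kb RI intervals in which donor ancestry is forced to high frequency in
  P2 while interlineage introgression into P1 is suppressed.  Used for
  painting, F_intro, RI-island delineation and the conditioned spectra.
* :func:`null_scenario` — no admixture at all, with equal site densities in
  every lineage; windowed D should be centred on zero.
"""

from __future__ import annotations

from .simulate import ScenarioParams

__all__ = ["pulse_scenario", "ri_scenario", "null_scenario", "RI_INTERVALS"]

RI_INTERVALS = (
    (1_500_000, 2_000_000),
    (4_500_000, 5_000_000),
    (7_500_000, 8_000_000),
)


def pulse_scenario(seed: int = 0, **overrides) -> ScenarioParams:
    """Ancient P3->P2 pulse only; no secondary contact, no background
    lineage variation (the private-variant signal channel in isolation)."""
    kw = dict(
        seed=seed,
        m=0.0,
        lam_shared=0.0,
        lam_p1=0.0,
        lam_p2=0.0,
        n_hap={"O": 2, "P3": 2, "P2": 28, "P1": 28},
    )
    kw.update(overrides)
    return ScenarioParams(**kw)


def ri_scenario(seed: int = 0, **overrides) -> ScenarioParams:
    """Pulse + secondary contact + three 500-kb RI intervals."""
    kw = dict(seed=seed, ri_intervals=RI_INTERVALS)
    kw.update(overrides)
    return ScenarioParams(**kw)


def null_scenario(seed: int = 0, **overrides) -> ScenarioParams:
    """No admixture; equal per-lineage site densities on a 2.5-Mb chromosome
    (50 windows of 50 kb)."""
    kw = dict(
        seed=seed,
        chrom_length=2_500_000,
        a=0.0,
        m=0.0,
        lam_p1=0.001,
        lam_p2=0.001,
        lam_p3=0.001,
        n_hap={"O": 2, "P3": 2, "P2": 28, "P1": 28},
    )
    kw.update(overrides)
    return ScenarioParams(**kw)
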