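"""Shared fixtures: simulated scenarios and the pipeline stages run on them.

The heavy simulations and HMM fits are session-scoped so the detection,
dating, RI and acceptance tests all reuse one run per scenario.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

import introscan as I
from introscan.scenarios import null_scenario, pulse_scenario, ri_scenario

PULSE_SEED = 7
RI_SEED = 11
NULL_SEED = 3


@pytest.fixture(scope="session")
def pulse_sim():
    params = pulse_scenario(seed=PULSE_SEED)
    panel, truth = I.simulate_panel(params)
    return params, panel, truth


@pytest.fixture(scope="session")
def pulse_archaic(pulse_sim):
    """Private-variant track, per-haplotype HMM fits and called tracts on
    the pulse scenario (focal P2 vs non-admixed P1)."""
    params, panel, truth = pulse_sim
    track = I.private_counts(panel, "P2", "P1", bin_bp=1000)
    models, post = I.fit_population(track)
    called = I.call_tracts(
        post, bin_bp=1000, hap_ids=track.hap_ids, chrom_length=params.chrom_length
    )
    return track, models, post, called


@pytest.fixture(scope="session")
def ri_sim():
    params = ri_scenario(seed=RI_SEED)
    panel, truth = I.simulate_panel(params)
    return params, panel, truth


@pytest.fixture(scope="session")
def ri_painting(ri_sim):
    """Painted P1 haplotypes and extracted Atlantic tracts on the RI scenario."""
    params, panel, truth = ri_sim
    model = I.CopyingModel.from_panel(panel, "P2", "P1R", r=params.r)
    hap_ids, p_atl = I.painting.paint_population(panel, "P1", model)
    tracts = I.extract_tracts(
        panel.positions,
        p_atl,
        chrom_length=params.chrom_length,
        hap_ids=hap_ids,
        ancestry="P2",
    )
    return hap_ids, p_atl, tracts


@pytest.fixture(scope="session")
def ri_islands(ri_sim, ri_painting):
    """Window-scale F_ST/F_intro ratio HMM islands on the RI scenario."""
    params, panel, truth = ri_sim
    hap_ids, _, tracts = ri_painting
    windows = I.make_windows(panel, span=50_000, min_snps=100)
    _, win_fst = I.weir_cockerham_fst(panel, "P1", "P2", windows)
    fintro = I.f_intro(tracts, windows)
    track = I.build_ratio(
        win_fst, fintro, scale="window", n_haplotypes=len(hap_ids), windows=windows
    )
    model, post = I.fit_hmm(track)
    islands = I.call_islands(track, post, chrom=params.chrom)
    return windows, track, model, post, islands


@pytest.fixture(scope="session")
def null_sim():
    params = null_scenario(seed=NULL_SEED)
    panel, truth = I.simulate_panel(params)
    return params, panel, truth


@pytest.fixture
def toy_panel():
    """Tiny hand-checkable panel: 2 haplotypes per population, 8 sites."""
    positions = np.array([5, 10, 20, 30, 40, 50, 60, 70])
    # rows: O x2, P3 x2, P2 x2, P1 x2
    alleles = np.array(
        [
            [0, 0, 0, 0, 0, 0, 0, 1],
            [0, 0, 0, 0, 0, 0, 0, 1],
            [1, 1, 0, 1, 0, 0, 1, 0],
            [1, 1, 0, 1, 0, 0, 1, 0],
            [1, 0, 1, 1, 0, 1, 0, 0],
            [1, 0, 0, 1, 0, 0, 0, 0],
            [0, 0, 1, 0, 1, 0, 0, 0],
            [0, 0, 0, 0, 1, 1, 0, 0],
        ],
        dtype=np.uint8,
    )
    pops = ["O", "O", "P3", "P3", "P2", "P2", "P1", "P1"]
    return I.HaplotypePanel(
        chrom="toy",
        positions=positions,
        alleles=alleles,
        hap_ids=[f"{p}_{i}" for i, p in enumerate(pops)],
        individuals=[f"{p}_{i // 2}" for i, p in enumerate(pops)],
        populations=np.array(pops, dtype=object),
        polarized=True,
        chrom_length=80,
    )
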