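"""Window statistics against arithmetic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import introscan as I
from introscan.panel import GenomicWindow
from oracles import dxy_pairs, spearman_hand, wc_fst_site


def _panel_from_rows(rows, pops, positions=None, chrom_length=None, polarized=True):
    rows = np.array(rows, dtype=np.uint8)
    if positions is None:
        positions = np.arange(rows.shape[1]) * 10
    return I.HaplotypePanel(
        chrom="t",
        positions=np.asarray(positions),
        alleles=rows,
        hap_ids=[f"h{i}" for i in range(rows.shape[0])],
        individuals=[f"i{i // 2}" for i in range(rows.shape[0])],
        populations=np.array(pops, dtype=object),
        polarized=polarized,
        chrom_length=chrom_length,
    )


def _one_window(panel, span=None):
    span = span or panel.chrom_length
    return [GenomicWindow(chrom=panel.chrom, start=0, end=span, n_snps=panel.n_sites)]


class TestDxy:
    def test_identical_haplotypes_zero(self):
        panel = _panel_from_rows([[0, 1, 0], [0, 1, 0]], ["A", "B"], chrom_length=100)
        assert I.dxy(panel, "A", "B", _one_window(panel))[0] == 0.0

    def test_five_differences_over_50kb(self):
        rows = [[1, 1, 1, 1, 1], [0, 0, 0, 0, 0]]
        panel = _panel_from_rows(rows, ["A", "B"], chrom_length=50_000)
        assert I.dxy(panel, "A", "B", _one_window(panel))[0] == pytest.approx(1.0e-4)

    def test_multi_haplotype_equals_pair_average(self):
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 2, size=(7, 40))
        pops = ["A"] * 3 + ["B"] * 4
        panel = _panel_from_rows(rows, pops, chrom_length=400)
        got = I.dxy(panel, "A", "B", _one_window(panel))[0]
        want = dxy_pairs(rows[:3], rows[3:], 400)
        assert got == pytest.approx(want, rel=1e-12)


class TestWeirCockerhamFst:
    def test_fixed_difference_is_one(self):
        rows = [[1]] * 4 + [[0]] * 4
        panel = _panel_from_rows(rows, ["A"] * 4 + ["B"] * 4, chrom_length=10)
        per_snp, _ = I.weir_cockerham_fst(panel, "A", "B")
        assert per_snp[0] == pytest.approx(1.0)

    def test_equal_frequencies_nonpositive(self):
        rows = [[1, 0], [0, 1], [1, 1], [0, 0]] * 2
        panel = _panel_from_rows(rows, ["A"] * 4 + ["B"] * 4, chrom_length=100)
        per_snp, _ = I.weir_cockerham_fst(panel, "A", "B")
        assert np.all(per_snp[np.isfinite(per_snp)] <= 0)

    def test_hand_dataset_matches_variance_components(self):
        # 4+4 haplotypes, mixed frequencies, checked site by site
        rows = [
            [1, 1, 0, 1, 0],
            [1, 0, 0, 1, 0],
            [1, 1, 0, 0, 0],
            [0, 1, 0, 1, 1],
            [0, 0, 1, 1, 0],
            [0, 0, 1, 0, 0],
            [1, 0, 0, 1, 0],
            [0, 0, 1, 0, 1],
        ]
        panel = _panel_from_rows(rows, ["A"] * 4 + ["B"] * 4, chrom_length=50)
        per_snp, per_window = I.weir_cockerham_fst(panel, "A", "B", _one_window(panel))
        arr = np.array(rows, dtype=float)
        for j in range(5):
            want = wc_fst_site(arr[:4, j].mean(), 4, arr[4:, j].mean(), 4)
            if np.isnan(want):
                assert np.isnan(per_snp[j])
            else:
                assert per_snp[j] == pytest.approx(want, rel=1e-12)

    def test_monomorphic_window_undefined(self):
        rows = [[0], [0], [0], [0]]
        panel = _panel_from_rows(rows, ["A", "A", "B", "B"], chrom_length=10)
        _, per_window = I.weir_cockerham_fst(panel, "A", "B", _one_window(panel))
        assert np.isnan(per_window[0])


class TestAbbaBaba:
    def _freq_panel(self, f1, f2, f3, f4, n=10):
        """Panel whose per-pop derived frequencies are exactly as given."""
        def col(f):
            k = int(round(f * n))
            return [1] * k + [0] * (n - k)

        rows = np.array([col(f1) + col(f2) + col(f3) + col(f4)]).T.reshape(4 * n, 1)
        pops = ["P1"] * n + ["P2"] * n + ["P3"] * n + ["O"] * n
        return _panel_from_rows(rows, pops, chrom_length=10)

    def test_perfect_abba_site(self):
        panel = self._freq_panel(0.0, 1.0, 1.0, 0.0)
        df = I.abba_baba(panel, _one_window(panel))
        assert df.abba_sum[0] == 1.0 and df.baba_sum[0] == 0.0
        assert df.D[0] == 1.0 and df.fD[0] == 1.0

    def test_symmetric_populations_give_zero_d(self):
        panel = self._freq_panel(0.6, 0.6, 0.8, 0.0)
        df = I.abba_baba(panel, _one_window(panel))
        assert df.D[0] == pytest.approx(0.0)
        assert np.isnan(df.fD[0])  # no positive excess to normalise

    def test_single_site_arithmetic(self):
        panel = self._freq_panel(0.2, 0.8, 1.0, 0.0)
        df = I.abba_baba(panel, _one_window(panel))
        assert df.abba_sum[0] == pytest.approx(0.64)
        assert df.baba_sum[0] == pytest.approx(0.04)
        assert df.D[0] == pytest.approx((0.64 - 0.04) / 0.68)
        assert df.fD[0] == pytest.approx(0.60 / 0.80)

    def test_no_informative_sites_d_undefined(self):
        panel = self._freq_panel(0.5, 0.5, 0.0, 0.0)
        df = I.abba_baba(panel, _one_window(panel))
        assert np.isnan(df.D[0])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_d_bounded_and_antisymmetric(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(16, 30))
        rows[12:] = 0  # outgroup ancestral
        pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["O"] * 4
        panel = _panel_from_rows(rows, pops, chrom_length=300)
        w = _one_window(panel)
        d = I.abba_baba(panel, w).D[0]
        d_swap = I.abba_baba(panel, w, p1="P2", p2="P1").D[0]
        if np.isfinite(d):
            assert -1.0 <= d <= 1.0
            assert d_swap == pytest.approx(-d)


class TestRndMin:
    def test_identical_donor_recipient_pair_zero(self):
        rows = [[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 0, 0]]
        panel = _panel_from_rows(rows, ["D", "R", "R", "O"], chrom_length=100)
        df = I.rnd_min(panel, "D", "R", "O", _one_window(panel))
        assert df.rnd_min[0] == 0.0

    def test_uniform_distances_ratio(self):
        # donor-recipient pairs all differ at 2 sites; outgroup at 4
        rows = [
            [1, 1, 0, 0, 0, 0],
            [1, 0, 1, 0, 0, 0],
            [0, 0, 0, 0, 1, 1],
        ]
        panel = _panel_from_rows(rows, ["D", "R", "O"], chrom_length=60)
        df = I.rnd_min(panel, "D", "R", "O", _one_window(panel))
        assert df.d_min[0] == pytest.approx(2 / 60)
        assert df.d_out[0] == pytest.approx(4 / 60)
        assert df.rnd_min[0] == pytest.approx(0.5)

    def test_minimum_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        rows = rng.integers(0, 2, size=(8, 25))
        pops = ["D"] * 3 + ["R"] * 3 + ["O"] * 2
        panel = _panel_from_rows(rows, pops, chrom_length=250)
        df = I.rnd_min(panel, "D", "R", "O", _one_window(panel))
        want = min(
            sum(int(x != y) for x, y in zip(rows[i], rows[j]))
            for i in range(3)
            for j in range(3, 6)
        )
        assert df.d_min[0] == pytest.approx(want / 250)

    def test_rnd_min_bounded_by_mean_distance(self, ri_sim):
        params, panel, _ = ri_sim
        w = I.make_windows(panel, span=100_000, min_snps=1)[:20]
        df = I.rnd_min(panel, "P3", "P2", "O", w)
        for _, row in df.iterrows():
            if np.isfinite(row.rnd_min):
                assert row.d_min <= row.d_out * row.rnd_min + 1e-12


class TestTopologyWeights:
    def _four_taxon_panel(self, n_per=2, p2_with_p3=True, seed=0):
        """Sites grouping P2 (or P1) haplotypes with the donor P3."""
        rng = np.random.default_rng(seed)
        n_sites = 60
        rows = np.zeros((4 * n_per, n_sites), dtype=np.uint8)
        pops = ["O"] * n_per + ["P3"] * n_per + ["P2"] * n_per + ["P1"] * n_per
        grouped = slice(n_per, 3 * n_per) if p2_with_p3 else None
        for j in range(n_sites):
            if j % 2 == 0:
                rows[n_per : 2 * n_per, j] = 1  # P3-specific background
            if grouped is not None and j % 3 == 0:
                rows[grouped, j] = 1  # P3+P2 synapomorphies
            if rng.random() < 0.2:
                rows[3 * n_per :, j] = 1  # P1 noise
        return _panel_from_rows(rows, pops, chrom_length=600)

    def test_donor_recipient_clustering_forces_topology(self):
        panel = self._four_taxon_panel()
        w = _one_window(panel)
        weights, degenerate = I.topology_weights(panel, w, seed=0)
        assert not degenerate[0]
        assert np.argmax(weights[0]) == 1  # P3 groups with P2
        assert weights[0, 1] > 0.9

    def test_weights_sum_to_one(self, ri_sim):
        _, panel, _ = ri_sim
        w = I.make_windows(panel, span=50_000, min_snps=1)[:5]
        weights, _ = I.topology_weights(panel, w, n_quartets=50, seed=1)
        np.testing.assert_allclose(weights.sum(axis=1), 1.0, atol=1e-12)

    def test_sampling_converges_to_enumeration(self):
        panel = self._four_taxon_panel(n_per=3, seed=3)
        w = _one_window(panel)
        full, _ = I.topology_weights(panel, w, enum_cap=100, seed=0)  # 81 combos
        sampled, _ = I.topology_weights(panel, w, enum_cap=1, n_quartets=500, seed=0)
        assert np.abs(full - sampled).max() < 0.05

    def test_no_variation_gives_uniform_degenerate(self):
        rows = np.zeros((8, 4), dtype=np.uint8)
        pops = ["O", "O", "P3", "P3", "P2", "P2", "P1", "P1"]
        panel = _panel_from_rows(rows, pops, chrom_length=40)
        weights, degenerate = I.topology_weights(panel, _one_window(panel))
        assert degenerate[0]
        np.testing.assert_allclose(weights[0], 1 / 3)


class TestCorrelateTracks:
    def test_monotone_pair_rho_one(self):
        a = np.array([1.0, 2, 3, 4, 5])
        rho, _ = I.correlate_tracks(a, a**2)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        a = np.array([1.0, 2, 3, 4, 5])
        rho, _ = I.correlate_tracks(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        a = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        b = [2.0, 7.0, 1.0, 8.0, 2.5, 0.5]
        rho, _ = I.correlate_tracks(a, b)
        assert rho == pytest.approx(spearman_hand(a, b), rel=1e-12)

    def test_too_few_complete_pairs_errors(self):
        a = [1.0, np.nan, 3.0, np.nan]
        b = [2.0, 1.0, np.nan, 4.0]
        with pytest.raises(ValueError):
            I.correlate_tracks(a, b)
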