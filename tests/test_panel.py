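"""Panel construction, VCF round-trips, polarization and window tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import introscan as I

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def _write_vcf(tmp_path, body, name="toy.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


POPMAP = {"S1": "P1", "S2": "P1", "S3": "P2"}


class TestLoadPanel:
    def test_complete_phased_vcf_gives_full_matrix(self, tmp_path):
        body = (
            "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n"
            "chr1\t20\t.\tG\tC\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1\n"
            "chr1\t30\t.\tC\tA\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1\n"
            "chr1\t40\t.\tT\tG\t.\tPASS\t.\tGT\t1|1\t1|0\t0|0\n"
        )
        panel = I.load_panel(_write_vcf(tmp_path, body), popmap=POPMAP)
        assert panel.alleles.shape == (6, 4)
        assert panel.positions.tolist() == [9, 19, 29, 39]  # 0-based internally
        np.testing.assert_array_equal(panel.alleles[:, 0], [0, 1, 1, 1, 0, 0])
        assert panel.populations.tolist() == ["P1", "P1", "P1", "P1", "P2", "P2"]

    def test_half_called_site_dropped(self, tmp_path):
        body = (
            "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n"
            "chr1\t20\t.\tG\tC\t.\tPASS\t.\tGT\t0|0\t.|1\t1|1\n"
            "chr1\t30\t.\tC\tA\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1\n"
            "chr1\t40\t.\tT\tG\t.\tPASS\t.\tGT\t1|1\t1|0\t0|0\n"
        )
        panel = I.load_panel(_write_vcf(tmp_path, body), popmap=POPMAP)
        assert panel.alleles.shape == (6, 3)
        assert panel.positions.tolist() == [9, 29, 39]

    def test_unknown_popmap_sample_errors(self, tmp_path):
        body = "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n"
        with pytest.raises(ValueError, match="X"):
            I.load_panel(_write_vcf(tmp_path, body), popmap={**POPMAP, "X": "P2"})

    def test_unphased_heterozygote_error_mode_names_sample(self, tmp_path):
        body = "chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t0/1\t0|0\n"
        with pytest.raises(ValueError, match="S2"):
            I.load_panel(_write_vcf(tmp_path, body), popmap=POPMAP, on_unphased="error")

    def test_write_load_round_trip(self, toy_panel, tmp_path):
        path = tmp_path / "rt.vcf"
        I.write_panel(toy_panel, path)
        popmap = {ind: pop for ind, pop in zip(toy_panel.individuals, toy_panel.populations)}
        back = I.load_panel(path, popmap=popmap)
        np.testing.assert_array_equal(back.alleles, toy_panel.alleles)
        np.testing.assert_array_equal(back.positions, toy_panel.positions)


class TestPolarize:
    def _panel(self, out_haps, in_haps):
        # rows: outgroup haplotypes first, then ingroup haplotypes
        alleles = np.array(out_haps + in_haps, dtype=np.uint8)
        pops = np.array(["O"] * len(out_haps) + ["P1"] * len(in_haps), dtype=object)
        return I.HaplotypePanel(
            chrom="c",
            positions=np.arange(alleles.shape[1]) * 10,
            alleles=alleles,
            hap_ids=[f"h{i}" for i in range(alleles.shape[0])],
            individuals=[f"i{i // 2}" for i in range(alleles.shape[0])],
            populations=pops,
        )

    def test_outgroup_fixed_derived_flips_site(self):
        # one site: outgroup 1/1, ingroup 1,0
        panel = self._panel([[1], [1]], [[1], [0]])
        out, keep = I.polarize(panel, "O")
        assert keep.tolist() == [True]
        np.testing.assert_array_equal(out.alleles[:, 0], [0, 0, 0, 1])

    def test_outgroup_fixed_ancestral_unchanged(self):
        panel = self._panel([[0], [0]], [[1], [0]])
        out, _ = I.polarize(panel, "O")
        np.testing.assert_array_equal(out.alleles[:, 0], [0, 0, 1, 0])

    def test_tied_outgroup_site_dropped(self):
        panel = self._panel([[1], [0]], [[1], [0]])
        out, keep = I.polarize(panel, "O")
        assert keep.tolist() == [False]
        assert out.n_sites == 0

    def test_involution_on_outgroup_fixed_sites(self, toy_panel):
        once, _ = I.polarize(toy_panel, "O")
        twice, keep = I.polarize(once, "O")
        assert keep.all()
        np.testing.assert_array_equal(twice.alleles, once.alleles)


class TestRecombinationMap:
    def test_tsv_round_trip_and_default(self, tmp_path):
        path = tmp_path / "recomb.tsv"
        path.write_text("chrom\tr_M_per_bp\nchr1\t3.693e-8\nchr2\t1e-8\n")
        rmap = I.read_recomb_map(path, default=2e-8)
        assert rmap.rate("chr1") == pytest.approx(3.693e-8)
        assert rmap.rate("chrX") == pytest.approx(2e-8)  # falls back to default
        with pytest.raises(KeyError):
            I.RecombinationMap(rates={"chr1": 1e-8}).rate("chr9")

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            I.RecombinationMap(rates={"chr1": 0.0})


class TestWindows:
    def test_terminal_window_shorter(self):
        w = I.make_windows(np.array([5]), span=50_000, min_snps=0, chrom_length=120_000)
        assert [(x.start, x.end) for x in w] == [(0, 50_000), (50_000, 100_000), (100_000, 120_000)]

    def test_min_snps_exclusion_flag(self):
        pos = np.sort(np.random.default_rng(0).choice(50_000, size=499, replace=False))
        w = I.make_windows(pos, span=50_000, min_snps=500, chrom_length=50_000)
        assert w[0].n_snps == 499 and w[0].excluded
        w = I.make_windows(pos, span=50_000, min_snps=499, chrom_length=50_000)
        assert not w[0].excluded

    def test_empty_panel_all_excluded(self):
        w = I.make_windows(np.array([], dtype=int), span=50_000, min_snps=1, chrom_length=200_000)
        assert all(x.n_snps == 0 and x.excluded for x in w)

    @given(
        chrom_length=st.integers(min_value=1, max_value=500_000),
        span=st.integers(min_value=1, max_value=100_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_tiling_covers_chromosome_without_gaps(self, chrom_length, span):
        w = I.make_windows(np.array([], dtype=int), span=span, min_snps=0, chrom_length=chrom_length)
        assert w[0].start == 0 and w[-1].end == chrom_length
        for a, b in zip(w, w[1:]):
            assert a.end == b.start
        assert all(x.span == span for x in w[:-1])
        assert 0 < w[-1].span <= span
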