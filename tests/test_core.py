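"""Data model, windowing schemes and the repeat/missing-data site filter."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sporekit.core import (
    FormatError,
    Interval,
    RepeatAnnotation,
    VariantMatrix,
    filter_variants,
    fixed_windows,
    variable_site_windows,
)
from sporekit import io


def make_vm(alleles, positions=None, chrom="chr1", samples=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    n, m = alleles.shape
    samples = samples or [f"s{i}" for i in range(n)]
    positions = positions if positions is not None else np.arange(m) * 10
    return VariantMatrix(
        samples, {chrom: np.asarray(positions)}, {chrom: alleles}
    )


class TestInterval:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            Interval("chr1", 5, 5)

    def test_half_open_membership(self):
        iv = Interval("chr1", 10, 20)
        assert iv.contains(10) and iv.contains(19) and not iv.contains(20)


class TestFasta:
    def test_lengths_and_roundtrip(self, tmp_path):
        p = tmp_path / "toy.fa"
        p.write_text(">a\nACGTACGTAC\n>b\nGGGCCC\n")
        g = io.read_fasta(p)
        assert g.lengths == {"a": 10, "b": 6}
        out = tmp_path / "rt.fa"
        io.write_fasta(g, out)
        assert io.read_fasta(out).sequences == g.sequences

    def test_nonstandard_characters_become_n(self, tmp_path):
        p = tmp_path / "amb.fa"
        p.write_text(">a\nacgtr\n")
        assert io.read_fasta(p).sequences["a"] == "ACGTN"

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            io.read_fasta(p)


VCF_BODY = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t10\t.\tA\tC\t.\tPASS\t.\tGT\t0\t1\t0
chr1\t20\t.\tG\tT\t.\tPASS\t.\tGT\t1\t1\t0
chr1\t30\t.\tA\tAT\t.\tPASS\t.\tGT\t0\t0\t1
chr1\t40\t.\tC\tG\t.\tPASS\t.\tGT\t0\t.\t1
chr1\t50\t.\tT\tA\t.\tPASS\t.\tGT\t1\t0\t0
chr1\t60\t.\tT\tC\t.\tPASS\t.\tGT\t0\t0\t1
"""


class TestVcf:
    def test_snp_rows_only_and_missing_code(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(VCF_BODY)
        vm = io.read_variants(p)
        assert vm.samples == ["s1", "s2", "s3"]
        assert vm.n_sites("chr1") == 5  # indel row dropped
        # site at POS 40 (0-based 39): sample s2 missing
        j = int(np.where(vm.positions["chr1"] == 39)[0][0])
        assert vm.alleles["chr1"][1, j] == -1

    def test_roundtrip_identity(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(VCF_BODY)
        vm = io.read_variants(p)
        out = tmp_path / "rt.vcf"
        io.write_variants(vm, out, {"chr1": 1000})
        vm2 = io.read_variants(out)
        assert vm2.samples == vm.samples
        np.testing.assert_array_equal(vm2.positions["chr1"], vm.positions["chr1"])
        np.testing.assert_array_equal(vm2.alleles["chr1"], vm.alleles["chr1"])

    def test_diploid_genotype_names_sample(self, tmp_path):
        p = tmp_path / "dip.vcf"
        p.write_text(VCF_BODY.replace("GT\t0\t1\t0", "GT\t0/1\t1\t0", 1))
        with pytest.raises(io.ConfigurationError, match="s1"):
            io.read_variants(p)


class TestFilterVariants:
    def test_hand_count(self):
        # 5 sites; site at pos 20 inside a repeat, site at pos 30 has missing
        vm = make_vm(
            [[0, 1, 2, 3, 0], [0, 1, 2, -1, 1], [1, 1, 2, 3, 0]],
            positions=[0, 20, 25, 30, 40],
        )
        reps = [RepeatAnnotation(Interval("chr1", 18, 22), "fam")]
        out = filter_variants(vm, reps)
        assert list(out.positions["chr1"]) == [0, 25, 40]
        assert out.samples == vm.samples

    def test_no_filtering_is_identity(self):
        vm = make_vm([[0, 1], [1, 0], [2, 3]])
        out = filter_variants(vm, [])
        np.testing.assert_array_equal(out.alleles["chr1"], vm.alleles["chr1"])

    def test_all_missing_sample_removes_everything(self):
        vm = make_vm([[0, 1], [-1, -1], [2, 3]])
        assert filter_variants(vm, []).n_sites("chr1") == 0

    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(-1, 4, size=(4, 30)).astype(np.int8)
        vm = make_vm(mat)
        reps = [RepeatAnnotation(Interval("chr1", 50, 120), "fam")]
        once = filter_variants(vm, reps)
        twice = filter_variants(once, reps)
        np.testing.assert_array_equal(once.alleles["chr1"], twice.alleles["chr1"])
        np.testing.assert_array_equal(once.positions["chr1"], twice.positions["chr1"])


class TestVariableSiteWindows:
    @pytest.mark.parametrize(
        "n_total,n_sites,expected",
        [(120, 50, 2), (50, 50, 1), (5, 1, 5), (49, 50, 0)],
    )
    def test_window_counts(self, n_total, n_sites, expected):
        vm = make_vm(np.zeros((3, n_total), dtype=np.int8))
        wins = variable_site_windows(vm, "chr1", n_sites)
        assert len(wins) == expected

    def test_partition_is_disjoint_and_covers_prefix(self):
        vm = make_vm(np.zeros((3, 137), dtype=np.int8))
        wins = variable_site_windows(vm, "chr1", 25)
        covered = []
        for _, sl in wins:
            covered.extend(range(sl.start, sl.stop))
        assert covered == list(range(125))  # floor(137/25)*25

    def test_interval_spans_first_to_last_site(self):
        vm = make_vm(np.zeros((3, 4), dtype=np.int8), positions=[5, 9, 100, 140])
        (iv, _), = variable_site_windows(vm, "chr1", 4)
        assert (iv.start, iv.end) == (5, 141)

    def test_missing_chromosome_raises(self):
        vm = make_vm(np.zeros((3, 10), dtype=np.int8))
        with pytest.raises(KeyError):
            variable_site_windows(vm, "chrX", 5)


class TestFixedWindows:
    @pytest.mark.parametrize(
        "length,size,step,expected",
        [(10_000, 2_000, 2_000, 5), (10_000, 10_000, 2_000, 1), (10_000, 4_000, 2_000, 4)],
    )
    def test_window_counts(self, length, size, step, expected):
        assert len(fixed_windows("c", length, size, step)) == expected

    def test_tiling_when_step_equals_size(self):
        wins = fixed_windows("c", 10_500, 2_000, 2_000)
        assert [w.start for w in wins] == [0, 2000, 4000, 6000, 8000]
        for a, b in zip(wins, wins[1:]):
            assert a.end == b.start  # no overlap, no gap


class TestOtherReaders:
    def test_repeatmasker_toy(self, tmp_path):
        p = tmp_path / "toy.out"
        p.write_text(
            "   SW  perc perc perc  query  position in query  matching repeat\n"
            "score  div. del. ins.  sequence  begin  end  (left)  repeat  class/family  begin end (left) ID\n"
            "\n"
            "  463  10.1  0.0  0.0  chr1  101  200  (0)  +  Tad1  LINE  1  100  (0)  1\n"
            "  275  12.0  0.0  0.0  chr2  51  80  (0)  C  Gypsy  LTR  1  30  (0)  2\n"
        )
        reps = io.read_repeatmasker(p)
        assert [r.family for r in reps] == ["Tad1", "Gypsy"]
        assert (reps[0].interval.start, reps[0].interval.end) == (100, 200)

    def test_bed_fallback(self, tmp_path):
        p = tmp_path / "toy.bed"
        p.write_text("chr1\t100\t200\tTad1/LINE\t0\t+\n")
        (rep,) = io.read_repeatmasker(p)
        assert (rep.family, rep.repeat_class) == ("Tad1", "LINE")

    def test_bedgraph_half_open(self, tmp_path):
        p = tmp_path / "cov.bedgraph"
        p.write_text("chr1\t100\t104\t7\n")
        track = io.read_coverage(p)
        assert track.mean_depth(Interval("chr1", 100, 104)) == 7.0
        assert track.mean_depth(Interval("chr1", 104, 108)) == 0.0

    def test_gff_spliced_length_validity(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t200\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t1\t200\t.\t+\t.\tID=g1.t;Parent=g1\n"
            "chr1\tx\tCDS\t1\t60\t.\t+\t0\tID=c1;Parent=g1.t\n"
            "chr1\tx\tCDS\t101\t134\t.\t+\t0\tID=c2;Parent=g1.t\n"
        )
        (gene,) = io.read_gff(p)
        assert gene.spliced_length == 94
        assert not gene.valid

    def test_gff_coordinate_validation(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t90\t.\t+\t.\tID=g1\n"
            "chr1\tx\tCDS\t1\t90\t.\t+\t0\tID=c1;Parent=g1\n"
        )
        with pytest.raises(FormatError):
            io.read_gff(p, {"chr1": 50})
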