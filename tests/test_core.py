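"""Core types, interval arithmetic and format round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regvar.core import (
    FormatError,
    GenomicInterval,
    ValidationError,
    Variant,
    intersect_intervals,
    io,
)


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestTypes:
    def test_variant_invariants(self):
        with pytest.raises(ValidationError):
            Variant("chr1", 0, "A", "G")
        with pytest.raises(ValidationError):
            Variant("chr1", 10, "A", "A")
        with pytest.raises(ValidationError):
            Variant("", 10, "A", "G")
        with pytest.raises(ValidationError):
            Variant("chr1", 10, "A", "X")
        # deletion convention: empty alt is a valid allele
        v = Variant("chr1", 10, "G", "", "del1")
        assert v.alt == ""

    def test_interval_invariants(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 5)

    def test_chr_prefix_stripped_in_comparisons(self):
        assert iv("chr1", 0, 10).overlap_bp(iv("1", 5, 15)) == 5
        assert Variant("1", 6, "A", "G").norm_chrom == iv("chr1", 0, 10).norm_chrom


class TestIntersect:
    def test_basic_overlap(self):
        out = intersect_intervals([iv("chr1", 100, 200)], [iv("chr1", 150, 250)])
        assert len(out) == 1
        assert out[0][2] == 50

    def test_half_open_boundary_no_overlap(self):
        assert intersect_intervals([iv("chr1", 100, 200)], [iv("chr1", 200, 300)]) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)

        def random_set(n):
            out = []
            for _ in range(n):
                chrom = rng.choice(["chr1", "chr2"])
                start = int(rng.integers(0, 500))
                out.append(iv(chrom, start, start + int(rng.integers(1, 80))))
            return out

        a, b = random_set(50), random_set(50)
        got = intersect_intervals(a, b)
        brute = []
        for x in a:
            for y in b:
                ov = x.overlap_bp(y)
                if ov >= 1:
                    brute.append((x, y, ov))
        brute.sort(key=lambda t: (t[0].norm_chrom, t[0].start, t[0].end, t[1].start, t[1].end))
        assert got == brute

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 50)), max_size=12),
           st.lists(st.tuples(st.integers(0, 200), st.integers(1, 50)), max_size=12))
    def test_symmetric_up_to_pair_order(self, raw_a, raw_b):
        a = [iv("chr1", s, s + w) for s, w in raw_a]
        b = [iv("chr1", s, s + w) for s, w in raw_b]
        ab = {(x.start, x.end, y.start, y.end, ov) for x, y, ov in intersect_intervals(a, b)}
        ba = {(y.start, y.end, x.start, x.end, ov) for x, y, ov in intersect_intervals(b, a)}
        assert ab == ba


class TestVariantIO:
    def test_vcf_row(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t8257959\trs72635708\tT\tC\t.\t.\t.\n"
        )
        (v,) = io.read_variants(str(p))
        assert (v.chrom, v.pos, v.ref, v.alt, v.vid) == ("1", 8257959, "T", "C", "rs72635708")

    def test_multiallelic_split(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\trs1\tA\tC,G\t.\t.\t.\n"
        )
        vs = io.read_variants(str(p))
        assert [v.alt for v in vs] == ["C", "G"]

    def test_tsv_bad_allele_reports_line(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("chrom\tpos\tid\tref\talt\n1\t100\trs1\tA\tZ\n")
        with pytest.raises(ValidationError, match="line 2"):
            io.read_variants(str(p), dialect="tsv")

    @pytest.mark.parametrize("dialect", ["vcf", "tsv"])
    def test_round_trip_random_variants(self, tmp_path, dialect):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        variants = []
        for i, pos in enumerate(sorted(rng.choice(10**6, size=100, replace=False) + 1)):
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            variants.append(Variant("chr1", int(pos), str(ref), str(alt), f"rs{i}"))
        p = tmp_path / f"v.{dialect}"
        io.write_variants(str(p), variants, dialect=dialect)
        assert io.read_variants(str(p), dialect=dialect) == variants


class TestJaspar:
    TOY = ">MA0000.1 TOY\nA [ 10 0 3 1 0 5 2 1 ]\nC [ 0 1 1 1 0 1 2 1 ]\nG [ 0 9 3 1 0 1 2 1 ]\nT [ 0 0 3 7 10 3 4 7 ]\n"

    def test_parse_width_and_names(self):
        (pfm,) = io.read_jaspar_pfms(self.TOY)
        assert pfm.width == 8
        assert (pfm.motif_id, pfm.name) == ("MA0000.1", "TOY")

    def test_header_with_real_style_id(self):
        (pfm,) = io.read_jaspar_pfms(">MA0491.1 JUND\nA [ 1 1 1 1 ]\nC [ 1 1 1 1 ]\nG [ 1 1 1 1 ]\nT [ 1 1 1 1 ]\n")
        assert pfm.motif_id == "MA0491.1" and pfm.name == "JUND"

    def test_ragged_rows_rejected(self):
        bad = ">M X\nA [ 1 2 ]\nC [ 1 ]\nG [ 1 2 ]\nT [ 1 2 ]\n"
        with pytest.raises(FormatError, match="ragged"):
            io.read_jaspar_pfms(bad)

    def test_round_trip(self, tmp_path):
        (pfm,) = io.read_jaspar_pfms(self.TOY)
        p = tmp_path / "m.jaspar"
        io.write_jaspar_pfms(str(p), [pfm])
        (back,) = io.read_jaspar_pfms(str(p))
        assert back.motif_id == pfm.motif_id
        assert np.array_equal(back.counts, pfm.counts)


class TestContactMatrixIO:
    def test_coo_symmetrization(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "# contact-matrix format=coo chrom=chr1 bin_size=10\n"
            "bin_i\tbin_j\tcount\n0\t1\t3\n0\t2\t1\n1\t2\t2\n0\t0\t5\n1\t1\t5\n2\t2\t5\n"
        )
        m = io.read_contact_matrix(str(p))
        assert m.counts[1, 0] == 3 and m.counts[2, 1] == 2

    def test_dense_max_symmetrize(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("# contact-matrix format=dense chrom=chr1 bin_size=10\n"
                     "0.0\t0.0\t0.0\n5.0\t0.0\t0.0\n0.0\t0.0\t0.0\n")
        m = io.read_contact_matrix(str(p))
        assert m.counts[2, 1] == 0
        assert m.counts[1, 0] == 5 and m.counts[0, 1] == 5

    def test_non_square_dense_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("# contact-matrix format=dense chrom=chr1 bin_size=10\n1\t2\n")
        with pytest.raises(FormatError, match="square"):
            io.read_contact_matrix(str(p))

    @pytest.mark.parametrize("fmt", ["dense", "coo"])
    def test_round_trip(self, tmp_path, fmt):
        from regvar.contacts import ContactMatrix

        rng = np.random.default_rng(11)
        raw = rng.poisson(4.0, size=(20, 20)).astype(float)
        m = ContactMatrix("chr1", 1000, np.maximum(raw, raw.T))
        p = tmp_path / "m.tsv"
        io.write_contact_matrix(str(p), m, fmt=fmt)
        back = io.read_contact_matrix(str(p))
        assert back.bin_size == 1000
        assert np.array_equal(back.counts, m.counts)
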