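"""LD computation: haplotype tables, r^2, expansion, panel I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regvar.core.types import ValidationError, Variant
from regvar.ld import (
    HaplotypePanel,
    PanelLookupError,
    UndefinedLDError,
    haplotype_counts,
    ld_expand,
    r_squared,
    r_squared_se,
    read_haplotype_panel,
    write_haplotype_panel,
)
from regvar.synthetic_data import gen_haplotype_panel


def make_panel(columns, positions=None):
    alleles = np.array(columns, dtype=np.uint8).T
    n = alleles.shape[1]
    positions = positions or [100 * (j + 1) for j in range(n)]
    variants = [Variant("1", positions[j], "A", "G", f"v{j}") for j in range(n)]
    return HaplotypePanel(alleles=alleles, variants=variants)


class TestPanel:
    def test_rejects_non_binary(self):
        with pytest.raises(ValidationError):
            make_panel([[0, 1, 2, 0], [0, 0, 0, 0]])

    def test_rejects_odd_haplotype_count(self):
        with pytest.raises(ValidationError, match="even"):
            make_panel([[0, 1, 0], [0, 1, 1]])


class TestHaplotypeCounts:
    def test_enumeration(self):
        p = make_panel([[0, 0, 1, 1], [0, 1, 0, 1]])
        assert np.array_equal(haplotype_counts(p, "v0", "v1"), np.ones((2, 2), dtype=int))

    def test_identical_columns_diagonal(self):
        p = make_panel([[0, 1, 0, 1], [0, 1, 0, 1]])
        table = haplotype_counts(p, "v0", "v1")
        assert table[0, 1] == 0 and table[1, 0] == 0
        assert table.sum() == p.n_haplotypes

    def test_matches_per_row_tally(self):
        rng = np.random.default_rng(5)
        cols = rng.integers(0, 2, size=(2, 40))
        p = make_panel(cols)
        table = haplotype_counts(p, "v0", "v1")
        brute = np.zeros((2, 2), dtype=int)
        for a, b in zip(cols[0], cols[1]):
            brute[a, b] += 1
        assert np.array_equal(table, brute)


class TestRSquared:
    def test_perfect_ld(self):
        p = make_panel([[0, 1, 0, 1], [0, 1, 0, 1]])
        assert r_squared(p, "v0", "v1").r2 == 1.0

    def test_independence(self):
        p = make_panel([[0, 0, 1, 1], [0, 1, 0, 1]])
        res = r_squared(p, "v0", "v1")
        assert res.r2 == 0.0 and res.d == 0.0

    def test_monomorphic_raises(self):
        p = make_panel([[0, 0, 0, 0], [0, 1, 0, 1]])
        with pytest.raises(UndefinedLDError, match="monomorphic"):
            r_squared(p, "v0", "v1")

    def test_matches_correlation_oracle_on_random_panels(self):
        """r^2 equals the squared Pearson correlation of allele indicators."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            n = 2 * int(rng.integers(2, 26))
            cols = rng.integers(0, 2, size=(n, 2))
            if len(set(cols[:, 0])) < 2 or len(set(cols[:, 1])) < 2:
                continue
            p = make_panel(cols.T)
            got = r_squared(p, "v0", "v1").r2
            expected = np.corrcoef(cols[:, 0], cols[:, 1])[0, 1] ** 2
            assert got == pytest.approx(expected, abs=1e-12)
            checked += 1

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_relabel_invariance(self, seed):
        rng = np.random.default_rng(seed)
        cols = rng.integers(0, 2, size=(20, 2))
        if len(set(cols[:, 0])) < 2 or len(set(cols[:, 1])) < 2:
            return
        p = make_panel(cols.T)
        base = r_squared(p, "v0", "v1").r2
        assert r_squared(p, "v1", "v0").r2 == pytest.approx(base, abs=1e-15)
        flipped = make_panel((1 - cols).T)
        assert r_squared(flipped, "v0", "v1").r2 == pytest.approx(base, abs=1e-12)
        assert 0.0 <= base <= 1.0


class TestLDExpand:
    def test_strict_threshold_boundary(self):
        # a pair exactly at the threshold must be excluded; tag itself retained
        n = 40
        col_a = np.array([0, 1] * (n // 2))
        col_b = col_a.copy()
        col_b[:4] = 1 - col_b[:4]  # 10% discordant
        p = make_panel([col_a, col_b])
        r2 = r_squared(p, "v0", "v1").r2
        out = ld_expand(p, ["v0"], threshold=r2)
        assert [v.vid for _, v, _ in out] == ["v0"]  # exact-threshold pair excluded

    def test_just_above_threshold_retained(self):
        panel = gen_haplotype_panel(4000, [(0.4, 0.4, 0.82)], seed=3)
        res = r_squared(panel, "site_0", "site_1")
        out = ld_expand(panel, ["site_0"], threshold=0.8)
        ids = [v.vid for _, v, _ in out]
        if res.r2 > 0.8:
            assert ids == ["site_0", "site_1"]

    def test_planted_pair_recovered(self):
        panel = gen_haplotype_panel(
            2000, [(0.3, 0.3, 0.95), (0.3, 0.3, 0.5)], seed=1
        )
        out = ld_expand(panel, ["site_0"], threshold=0.8)
        ids = {v.vid for _, v, _ in out}
        assert ids == {"site_0", "site_1"}
        for _, v, res in out:
            assert res.r2 > 0.8 or v.vid == "site_0"

    def test_missing_tag_named_in_error(self):
        p = make_panel([[0, 1, 0, 1], [0, 0, 1, 1]])
        with pytest.raises(PanelLookupError, match="nope"):
            ld_expand(p, ["nope"], 0.8)

    def test_output_ordered_by_position(self):
        panel = gen_haplotype_panel(
            1000,
            [(0.4, 0.4, 0.99)],
            seed=9,
            variants=[Variant("1", 500, "A", "G", "b"), Variant("1", 100, "A", "G", "a")],
        )
        out = ld_expand(panel, ["b"], 0.8)
        assert [v.pos for _, v, _ in out] == sorted(v.pos for _, v, _ in out)


class TestGeneratorRecovery:
    @pytest.mark.parametrize("maf_a,maf_b,target", [(0.3, 0.3, 0.8), (0.2286, 0.2286, 0.9832)])
    def test_estimate_within_3se_envelope(self, maf_a, maf_b, target):
        panel = gen_haplotype_panel(2000, [(maf_a, maf_b, target)], seed=1)
        est = r_squared(panel, "site_0", "site_1").r2
        se = r_squared_se(maf_a, maf_b, target, 2000)
        assert abs(est - target) <= 3 * se


class TestPanelIO:
    def test_vcf_round_trip(self, tmp_path):
        panel = gen_haplotype_panel(40, [(0.3, 0.3, 0.7), (0.5, 0.5, 0.0)], seed=2)
        path = tmp_path / "panel.vcf"
        write_haplotype_panel(str(path), panel)
        back = read_haplotype_panel(str(path))
        assert back.n_haplotypes == panel.n_haplotypes
        for v in panel.variants:
            a = panel.alleles[:, panel.column(v.vid)]
            b = back.alleles[:, back.column(v.vid)]
            assert np.array_equal(a, b)

    def test_multiallelic_rejected(self, tmp_path):
        p = tmp_path / "m.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\n"
            "1\t100\trs1\tA\tC,G\t.\t.\t.\tGT\t0|1\n"
        )
        with pytest.raises(ValidationError, match="multi-allelic"):
            read_haplotype_panel(str(p))
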