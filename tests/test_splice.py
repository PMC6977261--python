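"""Maximum-entropy splice models, scoring, the |delta| > 5 rule, windows."""

import numpy as np
import pytest

from regvar.core.types import GeneModel, GenomicInterval, ValidationError, Variant, revcomp
from regvar.splice import (
    ConvergenceError,
    MarginalConstraint,
    SpliceModel,
    acceptor_window,
    all_kmers,
    donor_window,
    marginal_of,
    mem_fit,
    pwm_limit_model,
    splice_delta,
    splice_score,
)


class TestMemFit:
    def test_single_position_constraints_give_product_distribution(self):
        rng = np.random.default_rng(0)
        for k in (2, 3, 4):
            margs = rng.dirichlet(np.ones(4), size=k)
            model = mem_fit(k, [MarginalConstraint((i,), margs[i]) for i in range(k)])
            product = pwm_limit_model(k, margs)
            tv = 0.5 * np.abs(model.signal - product.signal).sum()
            assert tv < 1e-8

    def test_full_pairwise_constraint_reproduced_exactly(self):
        rng = np.random.default_rng(1)
        pair = rng.dirichlet(np.ones(16)).reshape(4, 4)
        model = mem_fit(2, [MarginalConstraint((0, 1), pair)])
        assert np.allclose(model.signal.reshape(4, 4), pair, atol=1e-12)

    def test_first_and_second_order_marginals_of_sample_matched(self):
        rng = np.random.default_rng(2)
        k = 3
        sample = rng.dirichlet(np.ones(4**k))
        constraints = [
            MarginalConstraint((i,), marginal_of(sample, k, (i,))) for i in range(k)
        ] + [
            MarginalConstraint((i, i + 1), marginal_of(sample, k, (i, i + 1)))
            for i in range(k - 1)
        ]
        model = mem_fit(k, constraints, tol=1e-10)
        for c in constraints:
            got = marginal_of(model.signal, k, c.positions)
            assert np.abs(got - c.table).max() < 1e-8

    def test_inconsistent_constraints_raise(self):
        only_a = np.array([1.0, 0, 0, 0])
        no_a = np.array([0.0, 1 / 3, 1 / 3, 1 / 3])
        with pytest.raises(ConvergenceError):
            mem_fit(2, [MarginalConstraint((0,), only_a), MarginalConstraint((0,), no_a)])

    def test_unordered_position_subset(self):
        """Constraints on (2, 0) are honored in the order given."""
        rng = np.random.default_rng(3)
        pair = rng.dirichlet(np.ones(16)).reshape(4, 4)
        model = mem_fit(3, [MarginalConstraint((2, 0), pair)])
        assert np.abs(marginal_of(model.signal, 3, (2, 0)) - pair).max() < 1e-10


class TestSpliceScore:
    def test_identity_model_scores_zero(self):
        k = 2
        model = SpliceModel(kind="generic", k=k, signal=np.full(16, 1 / 16))
        for seq in all_kmers(k):
            assert splice_score(model, seq).score == pytest.approx(0.0, abs=1e-12)

    def test_doubled_mass_closed_form(self):
        # uniform null; signal doubles AA's mass and renormalizes the rest
        k = 2
        signal = np.full(16, 1 / 16)
        signal[0] *= 2
        signal /= signal.sum()  # AA now 2/17ths of mass... keep exact arithmetic
        model = SpliceModel(kind="generic", k=k, signal=signal)
        expected = np.log2((2 / 16 / (17 / 16)) / (1 / 16))
        assert splice_score(model, "AA").score == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_signal_probability(self):
        rng = np.random.default_rng(4)
        signal = rng.dirichlet(np.ones(16))
        model = SpliceModel(kind="generic", k=2, signal=signal)
        kmers = all_kmers(2)
        scores = [splice_score(model, s).score for s in kmers]
        order_p = np.argsort(signal)
        assert np.all(np.diff(np.array(scores)[order_p]) >= -1e-12)

    def test_zero_signal_probability_rejected(self):
        signal = np.zeros(16)
        signal[1:] = 1 / 15
        model = SpliceModel(kind="generic", k=2, signal=signal)
        with pytest.raises(ValidationError, match="zero signal"):
            splice_score(model, "AA")

    def test_length_mismatch_rejected(self):
        model = SpliceModel(kind="generic", k=2, signal=np.full(16, 1 / 16))
        with pytest.raises(ValidationError, match="length"):
            splice_score(model, "AAA")


class TestSpliceDelta:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(5)
        return SpliceModel(kind="generic", k=3, signal=rng.dirichlet(np.ones(64)))

    def test_published_score_pair_is_candidate(self, model):
        """A (5.463, -1.440) score pair has delta 6.903, above the rule."""
        delta = 5.463 - (-1.440)
        assert delta == pytest.approx(6.903)
        assert abs(delta) > 5

    def test_strict_threshold(self, model):
        # synthesize two sequences and check rule strictness on their delta
        s_p, s_r, delta, cand = splice_delta(model, "ACG", "ACT")
        assert cand is (abs(delta) > 5)
        # scores exactly 5 apart are NOT candidates (strict >)
        sig = np.full(64, 1.0)
        sig[0] = 32.0  # AAA
        sig /= sig.sum()
        m2 = SpliceModel(kind="generic", k=3, signal=sig)
        d = splice_score(m2, "AAA").score - splice_score(m2, "AAC").score
        assert d == pytest.approx(5.0, abs=1e-12)
        assert splice_delta(m2, "AAA", "AAC")[3] is False

    def test_antisymmetry(self, model):
        s_p, s_r, d1, c1 = splice_delta(model, "ACG", "TCG")
        s_p2, s_r2, d2, c2 = splice_delta(model, "TCG", "ACG")
        assert d1 == pytest.approx(-d2, abs=1e-12)
        assert c1 == c2

    def test_identical_sequences_rejected(self, model):
        with pytest.raises(ValidationError, match="do not alter"):
            splice_delta(model, "ACG", "ACG")


def _toy_locus():
    # exon1 [50,100), intron, exon2 [150,200) on a 300-bp chromosome
    rng = np.random.default_rng(6)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    genome = {"chr1": seq}
    exons = (
        GenomicInterval("chr1", 50, 100, "+"),
        GenomicInterval("chr1", 150, 200, "+"),
    )
    gene = GeneModel("G", 51, "+", "T1", exons)
    return genome, gene


class TestWindows:
    def test_plus_strand_donor_coordinates(self):
        genome, gene = _toy_locus()
        # exon ending at 1-based position 100 -> 0-based boundary 100
        ref, _ = donor_window(genome, gene, 100)
        assert ref == genome["chr1"][97:106]
        assert len(ref) == 9

    def test_minus_strand_mirror(self):
        genome, _ = _toy_locus()
        exons = (GenomicInterval("chr1", 150, 200, "-"),)
        gene_minus = GeneModel("G", 200, "-", "T2", exons)
        # minus-strand exon starting (genomically) at 150: donor runs into intron leftward
        ref, _ = donor_window(genome, gene_minus, 150)
        assert ref == revcomp(genome["chr1"][144:153])

    def test_variant_substitution_index(self):
        genome, gene = _toy_locus()
        # intronic +2 base of the window (0-based genomic 101) is window index 4
        base = genome["chr1"][101]
        alt_base = "A" if base != "A" else "C"
        v = Variant("chr1", 102, base, alt_base, "rsW")
        ref, alt = donor_window(genome, gene, 100, v)
        diffs = [i for i, (x, y) in enumerate(zip(ref, alt)) if x != y]
        assert diffs == [4]

    def test_variant_outside_window_rejected(self):
        genome, gene = _toy_locus()
        base = genome["chr1"][120]
        v = Variant("chr1", 121, base, "A" if base != "A" else "C", "rsO")
        with pytest.raises(ValidationError, match="outside"):
            donor_window(genome, gene, 100, v)

    def test_acceptor_window_length_and_composition(self):
        genome, gene = _toy_locus()
        # exon2 starts at 0-based 150: 20 intronic + 3 exonic
        ref, _ = acceptor_window(genome, gene, 150)
        assert len(ref) == 23
        assert ref == genome["chr1"][130:153]
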