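"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is seeded and reproducible; the locus fixture realizes a
long-range enhancer scenario: a tag SNP in tight LD with a functional
variant sitting on the last base of a planted AP-1-like motif inside an
enhancer ~170 kb from its target gene's TSS, backed by an
enhancer-promoter link, a significant fibroblast eQTL, a ChIP-seq peak and
a planted Hi-C loop between the promoter and enhancer bins.

Ground truth is returned alongside every dataset so downstream stages can
be scored without reference to generator internals. Genome background is
uniform over ACGT; motifs replace background bases in place, keeping
coordinates stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .core.types import GeneModel, GenomicInterval, GWASCatalogRecord, Variant, revcomp
from .ld import HaplotypePanel
from .peak_stats import Peak
from .regulatory import EPLink
from .tfbs import PFM

BASES = "ACGT"


# ---------------------------------------------------------------------------
# haplotypes


def haplotype_frequencies(maf_a: float, maf_b: float, target_r2: float) -> np.ndarray:
    """Four-haplotype frequencies (00, 01, 10, 11) at the target r^2.

    D is taken positive (alternate alleles co-occur) with
    D = sqrt(r^2 * p_a q_a p_b q_b). Raises when the combination is
    infeasible, stating the feasible r^2 maximum at these frequencies.
    """
    pa, pb = maf_a, maf_b
    qa, qb = 1 - pa, 1 - pb
    d = np.sqrt(target_r2 * pa * qa * pb * qb)
    d_max = min(qa * pb, pa * qb)
    if d > d_max + 1e-12:
        r2_max = d_max**2 / (pa * qa * pb * qb)
        raise ValueError(
            f"target r^2={target_r2} infeasible at allele frequencies "
            f"({maf_a}, {maf_b}); maximum feasible r^2 is {r2_max:.4f}"
        )
    freqs = np.array([qa * qb + d, qa * pb - d, pa * qb - d, pa * pb + d])
    return np.clip(freqs, 0.0, 1.0)


def gen_haplotype_panel(
    n_haplotypes: int,
    pairs: Sequence[Tuple[float, float, float]],
    seed: int,
    variants: Optional[Sequence[Variant]] = None,
    population: str = "synthetic",
) -> HaplotypePanel:
    """Sample a phased panel with one two-locus block per (maf_a, maf_b, r2).

    Blocks are mutually independent; within a block, haplotypes are drawn
    from the four-haplotype multinomial at the target r^2. ``variants``
    optionally labels the 2 * len(pairs) columns (default: auto-named sites
    on chromosome 1).
    """
    if n_haplotypes % 2 != 0:
        raise ValueError("n_haplotypes must be even")
    rng = np.random.default_rng(seed)
    columns = []
    for maf_a, maf_b, r2 in pairs:
        freqs = haplotype_frequencies(maf_a, maf_b, r2)
        draws = rng.choice(4, size=n_haplotypes, p=freqs / freqs.sum())
        columns.append((draws >= 2).astype(np.uint8))  # allele at site a
        columns.append((draws % 2).astype(np.uint8))   # allele at site b
    alleles = np.stack(columns, axis=1)
    if variants is None:
        variants = [
            Variant("1", 1000 * (j + 1), "A", "G", f"site_{j}") for j in range(alleles.shape[1])
        ]
    return HaplotypePanel(alleles=alleles, variants=list(variants), population=population)


# ---------------------------------------------------------------------------
# contact maps


def gen_contact_map(
    n_bins: int,
    bin_size: int,
    seed: int,
    depth: float = 100.0,
    alpha: float = 1.0,
    tad_bins: Sequence[Tuple[int, int]] = (),
    tau: float = 1.0,
    loop: Optional[Tuple[int, int]] = None,
    lam: float = 1.0,
    chrom: str = "chr1",
) -> Tuple[ContactMatrix, dict]:
    """Poisson contact counts with power-law decay, TAD blocks and one loop.

    mean(i, j) = depth * (|i - j| + 1)^(-alpha) * tau^[same TAD] * lam^[loop pair].

    Returns the symmetric matrix plus ground truth (TAD bin ranges, the loop
    pair, and the expected-mean grid).
    """
    rng = np.random.default_rng(seed)
    i, j = np.indices((n_bins, n_bins))
    mean = depth * np.power(np.abs(i - j) + 1.0, -alpha)
    for lo, hi in tad_bins:
        inside = (i >= lo) & (i < hi) & (j >= lo) & (j < hi)
        mean = np.where(inside, mean * tau, mean)
    if loop is not None:
        a, b = loop
        mean[a, b] *= lam
        mean[b, a] *= lam
    upper = np.triu(rng.poisson(mean).astype(float))
    counts = upper + np.triu(upper, 1).T
    matrix = ContactMatrix(chrom=chrom, bin_size=bin_size, counts=counts)
    truth = {
        "tad_bins": list(tad_bins),
        "loop": loop,
        "loop_factor": lam,
        "tau": tau,
        "alpha": alpha,
        "depth": depth,
        "mean": mean,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# motif-partitioned peaks


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _embed_motifs(
    rng: np.random.Generator,
    length: int,
    embed: Sequence[str],
    forbidden: Sequence[str],
    max_tries: int = 200,
) -> str:
    """A sequence of the given length containing each motif in ``embed``
    exactly once and no occurrence of any ``forbidden`` motif (both strands
    checked for both sets)."""
    slots = np.linspace(0, length - 1, num=len(embed) + 2, dtype=int)[1:-1] if embed else []
    for _ in range(max_tries):
        seq = list(_random_seq(rng, length))
        for motif, at in zip(embed, slots):
            start = min(int(at), length - len(motif))
            seq[start : start + len(motif)] = motif
        s = "".join(seq)
        ok = all(_count_both(s, m) == 1 for m in embed) and all(
            _count_both(s, m) == 0 for m in forbidden
        )
        if ok:
            return s
    raise RuntimeError("could not generate a clean motif-bearing sequence")


def _count_both(seq: str, motif: str) -> int:
    return _count(seq, motif) + (_count(seq, revcomp(motif)) if revcomp(motif) != motif else 0)


def _count(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def gen_motif_peaks(
    n_a: int,
    n_b: int,
    n_both: int,
    n_neither: int,
    mu: float,
    sigma: float,
    delta: float,
    motif_a: str,
    motif_b: str,
    seed: int,
    peak_length: int = 200,
    chrom: str = "chrP",
) -> Tuple[List[Peak], Dict[str, str]]:
    """Peaks whose signals are log-normal, with a log-scale shift ``delta``
    favoring the motif-a group.

    Group-a peaks embed ``motif_a`` with signal ~ LogNormal(mu + delta,
    sigma); group-b peaks embed ``motif_b`` with signal ~ LogNormal(mu,
    sigma); dual-motif and motif-free peaks are generated as specified.
    Peak names encode the planted group (``a_``, ``b_``, ``both_``,
    ``neither_``). Sequences are embedded into one synthetic chromosome.
    """
    motif_a, motif_b = motif_a.upper(), motif_b.upper()
    if motif_a == motif_b or len(motif_a) != len(motif_b):
        raise ValueError("motifs must be distinct and of equal length")
    rng = np.random.default_rng(seed)
    gap = 50
    specs = (
        [("a", [motif_a], [motif_b], delta)] * n_a
        + [("b", [motif_b], [motif_a], 0.0)] * n_b
        + [("both", [motif_a, motif_b], [], 0.0)] * n_both
        + [("neither", [], [motif_a, motif_b], 0.0)] * n_neither
    )
    chrom_parts: List[str] = []
    peaks: List[Peak] = []
    pos = 0
    for idx, (label, embed, forbidden, shift) in enumerate(specs):
        flank = _random_seq(rng, gap)
        # keep inter-peak flanks motif-free so partition truth is exact
        while any(_count_both(flank, m) for m in (motif_a, motif_b)):
            flank = _random_seq(rng, gap)
        seq = _embed_motifs(rng, peak_length, embed, forbidden)
        signal = float(np.exp(rng.normal(mu + shift, sigma)))
        chrom_parts.extend([flank, seq])
        start = pos + gap
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, start + peak_length),
                signal=signal,
                name=f"{label}_{idx}",
                sequence=seq,
            )
        )
        pos = start + peak_length
    genome = {chrom: "".join(chrom_parts)}
    return peaks, genome


# ---------------------------------------------------------------------------
# the full locus fixture


@dataclass
class LocusSpec:
    """Parameters of the synthetic long-range-enhancer locus.

    Defaults emulate the study conditions: a ~170 kb TSS-to-enhancer
    separation, a tag SNP at r^2 = 0.9832 with the functional variant, risk
    allele frequency 0.2286, an AP-1-like 8-mer whose last base the variant
    substitutes (T > C), a significant fibroblast eQTL with negative effect
    size, and a Hi-C loop joining the promoter and enhancer bins.
    """

    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    gene: str = "ERRFI1"
    tss: int = 200_001  # 1-based; transcript on the plus strand
    gene_strand: str = "+"
    enhancer_offset: int = 170_000  # enhancer start relative to 0-based TSS
    enhancer_length: int = 278
    motif_consensus: str = "TGAGTCAT"
    variant_offset_in_motif: int = 7  # last motif base
    risk_allele: str = "C"
    ep_correlation: float = 0.6
    eqtl_nes: float = -0.35
    eqtl_significant: bool = True
    eqtl_tissue: str = "fibroblasts"
    bin_size: int = 10_000
    decay_alpha: float = 1.0
    tad_intervals: Tuple[Tuple[int, int], ...] = ((100_000, 500_000), (500_000, 900_000))
    tad_tau: float = 1.5
    loop_factor: float = 4.0
    depth: float = 100.0
    peak_mu: float = 3.0
    peak_sigma: float = 1.0
    peak_delta: float = 0.5
    n_haplotypes: int = 2000
    risk_allele_freq: float = 0.2286
    target_r2: float = 0.9832
    seed: int = 42

    @property
    def tss0(self) -> int:
        return self.tss - 1

    @property
    def enhancer_interval(self) -> GenomicInterval:
        start = self.tss0 + self.enhancer_offset
        return GenomicInterval(self.chrom, start, start + self.enhancer_length)

    @property
    def motif_start0(self) -> int:
        iv = self.enhancer_interval
        return iv.start + (len(iv) - len(self.motif_consensus)) // 2

    @property
    def variant_pos(self) -> int:
        """1-based position of the functional variant."""
        return self.motif_start0 + self.variant_offset_in_motif + 1


@dataclass
class LocusBundle:
    """All pipeline inputs for one synthetic locus, plus ground truth."""

    genome: Dict[str, str]
    genes: List[GeneModel]
    panel: HaplotypePanel
    gwas: List[GWASCatalogRecord]
    ep_links: List[EPLink]
    eqtl: pd.DataFrame
    pfms: List[PFM]
    peaks: List[Peak]
    matrix: ContactMatrix
    tads: List[GenomicInterval]
    truth: dict = field(default_factory=dict)


def _ap1_like_pfm(consensus: str) -> PFM:
    """A JUND-style PFM: strong consensus everywhere, with the terminal base
    tolerating the risk substitution at reduced frequency."""
    counts = np.full((4, len(consensus)), 5.0)
    for i, b in enumerate(consensus):
        counts[BASES.index(b), i] = 85.0
    counts[:, -1] = [10.0, 25.0, 5.0, 60.0]  # A C G T at the variant base
    return PFM(motif_id="MA0491.1", name="JUND", counts=counts)


def gen_locus_fixture(spec: LocusSpec = LocusSpec()) -> LocusBundle:
    """Generate the full input bundle realizing the planted enhancer story."""
    rng = np.random.default_rng(spec.seed)
    motif = spec.motif_consensus.upper()

    # genome with the motif planted inside the enhancer
    seq = list(_random_seq(rng, spec.chrom_length))
    m0 = spec.motif_start0
    seq[m0 : m0 + len(motif)] = motif
    genome = {spec.chrom: "".join(seq)}

    var_pos0 = spec.variant_pos - 1
    ref_allele = genome[spec.chrom][var_pos0]
    functional = Variant(spec.chrom, spec.variant_pos, ref_allele, spec.risk_allele, "rs72635708")

    # tag SNP 1 kb upstream of the enhancer
    tag_pos0 = spec.enhancer_interval.start - 1000
    tag_ref = genome[spec.chrom][tag_pos0]
    tag_alt = "A" if tag_ref != "A" else "G"
    tag = Variant(spec.chrom, tag_pos0 + 1, tag_ref, tag_alt, "rs417065")

    # two decoy variants in linkage equilibrium with everything
    decoys = []
    for k, off in enumerate((spec.chrom_length // 20, int(spec.chrom_length * 0.62))):
        ref = genome[spec.chrom][off]
        alt = "C" if ref != "C" else "T"
        decoys.append(Variant(spec.chrom, off + 1, ref, alt, f"rs_decoy{k + 1}"))

    p = spec.risk_allele_freq
    panel = gen_haplotype_panel(
        spec.n_haplotypes,
        pairs=[(p, p, spec.target_r2), (0.3, 0.4, 0.0)],
        seed=int(rng.integers(2**31)),
        variants=[tag, functional, decoys[0], decoys[1]],
        population="synthetic-EUR",
    )

    gwas = [
        GWASCatalogRecord("rs417065", "Psoriasis", 8e-07, "StudyA", tag_alt),
        GWASCatalogRecord("rs_decoy1", "Rheumatoid arthritis", 1e-08, "StudyB", "C"),
    ]

    ep_links = [
        EPLink(
            enhancer=spec.enhancer_interval,
            gene=spec.gene,
            correlation=spec.ep_correlation,
            activity={
                "hepatocyte": 30.0,
                "fibroblast_dermal": 25.0,
                "epithelial_cell": 18.0,
                "keratinocyte": 10.0,
                "hepatic_stellate_cell": 8.0,
                "lung": 4.0,
                "T_cell": 2.0,
                "B_cell": 1.5,
                "monocyte": 1.0,
                "neutrophil": 0.5,
            },
        )
    ]

    eqtl = pd.DataFrame(
        {
            "variant_id": ["rs72635708", "rs72635708", "rs_decoy1"],
            "gene": [spec.gene, spec.gene, "OTHERGENE"],
            "tissue": [spec.eqtl_tissue, "liver", "whole_blood"],
            "nes": [spec.eqtl_nes, spec.eqtl_nes * 0.6, 0.1],
            "significant": [spec.eqtl_significant, False, True],
        }
    )

    pfms = [_ap1_like_pfm(motif)]

    # JUND-like peak over the enhancer plus unrelated background peaks
    peaks = [
        Peak(
            interval=GenomicInterval(spec.chrom, m0 - 80, m0 + len(motif) + 80),
            signal=25.0,
            name="peak_enhancer",
        )
    ]
    for k, frac in enumerate((0.12, 0.45, 0.7)):
        off = int(spec.chrom_length * frac)
        peaks.append(
            Peak(
                interval=GenomicInterval(spec.chrom, off, off + 200),
                signal=float(np.exp(rng.normal(spec.peak_mu, spec.peak_sigma))),
                name=f"peak_bg{k}",
            )
        )

    # gene model: two exons, TSS at the first exon start (plus strand)
    exons = (
        GenomicInterval(spec.chrom, spec.tss0, spec.tss0 + 200, spec.gene_strand),
        GenomicInterval(spec.chrom, spec.tss0 + 1_000, spec.tss0 + 2_000, spec.gene_strand),
    )
    genes = [
        GeneModel(
            gene=spec.gene, tss=spec.tss, strand=spec.gene_strand,
            transcript="TX1", exons=exons,
        )
    ]

    n_bins = spec.chrom_length // spec.bin_size
    promoter_bin = (spec.tss0 - 1) // spec.bin_size
    enhancer_bin = spec.enhancer_interval.start // spec.bin_size
    tad_bins = [(lo // spec.bin_size, hi // spec.bin_size) for lo, hi in spec.tad_intervals]
    matrix, contact_truth = gen_contact_map(
        n_bins=n_bins,
        bin_size=spec.bin_size,
        seed=int(rng.integers(2**31)),
        depth=spec.depth,
        alpha=spec.decay_alpha,
        tad_bins=tad_bins,
        tau=spec.tad_tau,
        loop=(promoter_bin, enhancer_bin),
        lam=spec.loop_factor,
        chrom=spec.chrom,
    )
    tads = [GenomicInterval(spec.chrom, lo, hi) for lo, hi in spec.tad_intervals]

    truth = {
        "candidate_variant": "rs72635708",
        "variant_pos": spec.variant_pos,
        "ref_allele": ref_allele,
        "risk_allele": spec.risk_allele,
        "gene": spec.gene,
        "tag": "rs417065",
        "target_r2": spec.target_r2,
        "motif_id": pfms[0].motif_id,
        "tf": pfms[0].name,
        "enhancer": spec.enhancer_interval,
        "promoter_bin": promoter_bin,
        "enhancer_bin": enhancer_bin,
        "loop_factor": spec.loop_factor,
        "contact_mean": contact_truth["mean"],
    }
    return LocusBundle(
        genome=genome, genes=genes, panel=panel, gwas=gwas, ep_links=ep_links,
        eqtl=eqtl, pfms=pfms, peaks=peaks, matrix=matrix, tads=tads, truth=truth,
    )


def write_bundle(bundle: LocusBundle, outdir: str) -> Dict[str, str]:
    """Write every input of the bundle as plain-text files; returns a map of
    input name -> path, also saved as manifest.json alongside the files."""
    import json
    from pathlib import Path

    from . import ld
    from .core import io as cio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(out / "genome.fa"),
        "genes": str(out / "genes.tsv"),
        "panel": str(out / "panel.vcf"),
        "gwas": str(out / "gwas.tsv"),
        "ep_links": str(out / "ep_links.tsv"),
        "eqtl": str(out / "eqtl.tsv"),
        "pfm": str(out / "motifs.jaspar"),
        "peaks": str(out / "peaks.bed"),
        "matrix": str(out / "matrix.tsv"),
        "tads": str(out / "tads.bed"),
    }
    cio.write_fasta(paths["genome"], bundle.genome)
    cio.write_gene_models(paths["genes"], bundle.genes)
    ld.write_haplotype_panel(paths["panel"], bundle.panel)
    cio.write_gwas_catalog(paths["gwas"], bundle.gwas)
    cio.write_ep_links(paths["ep_links"], bundle.ep_links)
    cio.write_eqtl_table(paths["eqtl"], bundle.eqtl)
    cio.write_jaspar_pfms(paths["pfm"], bundle.pfms)
    cio.write_peaks(paths["peaks"], bundle.peaks)
    cio.write_contact_matrix(paths["matrix"], bundle.matrix, fmt="coo")
    cio.write_tads(paths["tads"], bundle.tads)
    truth = {
        k: v
        for k, v in bundle.truth.items()
        if isinstance(v, (str, int, float, bool, list, tuple))
    }
    truth["enhancer"] = [
        bundle.truth["enhancer"].chrom,
        bundle.truth["enhancer"].start,
        bundle.truth["enhancer"].end,
    ]
    # manifest records file names relative to its own directory so a bundle
    # is byte-identical wherever it is written
    manifest = {"inputs": {k: Path(v).name for k, v in paths.items()}, "truth": truth}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = str(out / "manifest.json")
    return paths
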