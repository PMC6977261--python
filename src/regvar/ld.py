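"""Linkage disequilibrium from phased haplotypes and LD expansion of tag SNPs.

LD is computed from phased 0/1 haplotype matrices only (the source panels are
phased); no EM estimator for unphased genotypes is provided. Multi-allelic
sites are rejected with an explicit error rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .core.types import ValidationError, Variant


class UndefinedLDError(ValueError):
    """r^2 is undefined because a site is monomorphic in the panel."""


class PanelLookupError(KeyError):
    """A requested variant id is not indexed in the haplotype panel."""


@dataclass
class HaplotypePanel:
    """Phased allele matrix, shape (n_haplotypes, n_sites), entries 0/1.

    ``variants[j]`` describes column ``j``; ``index`` maps variant id to its
    column. ``n_haplotypes`` must be even (two haplotypes per diploid sample).
    """

    alleles: np.ndarray
    variants: List[Variant]
    population: str = ""
    index: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValidationError("allele matrix must be 2-D (haplotypes x sites)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValidationError("allele matrix entries must be 0/1")
        if self.alleles.shape[0] % 2 != 0:
            raise ValidationError("n_haplotypes must be even (paired per diploid sample)")
        if len(self.variants) != self.alleles.shape[1]:
            raise ValidationError(
                f"{len(self.variants)} variants for {self.alleles.shape[1]} columns"
            )
        if not self.index:
            self.index = {v.vid: j for j, v in enumerate(self.variants)}
        if len(self.index) != len(self.variants):
            raise ValidationError("variant ids must map one-to-one onto columns")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def column(self, vid: str) -> int:
        try:
            return self.index[vid]
        except KeyError:
            raise PanelLookupError(f"variant {vid!r} not in panel") from None


@dataclass(frozen=True)
class LDResult:
    """Pairwise LD between two sites: raw coefficient D and r^2."""

    variant_a: str
    variant_b: str
    r2: float
    d: float
    n_haplotypes: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValidationError(f"r2 out of [0,1]: {self.r2}")


def haplotype_counts(panel: HaplotypePanel, site_a: str, site_b: str) -> np.ndarray:
    """2x2 haplotype count table; cell [i, j] counts haplotypes with allele i
    at ``site_a`` and allele j at ``site_b``. Sums to n_haplotypes."""
    a = panel.alleles[:, panel.column(site_a)]
    b = panel.alleles[:, panel.column(site_b)]
    table = np.zeros((2, 2), dtype=int)
    np.add.at(table, (a, b), 1)
    return table


def r_squared(panel: HaplotypePanel, site_a: str, site_b: str) -> LDResult:
    """Squared allelic correlation r^2 = D^2 / (p_a q_a p_b q_b).

    D = f11 - p_a p_b from haplotype frequencies. Raises
    :class:`UndefinedLDError` when either site is monomorphic (never a silent
    0 or NaN). Symmetric in its arguments.
    """
    n = panel.n_haplotypes
    table = haplotype_counts(panel, site_a, site_b)
    f = table / n
    p_a = f[1, :].sum()
    p_b = f[:, 1].sum()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedLDError(
            f"LD undefined: monomorphic site among ({site_a!r}, {site_b!r}) "
            f"(allele-1 frequencies {p_a:.4g}, {p_b:.4g})"
        )
    d = f[1, 1] - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(site_a, site_b, float(min(r2, 1.0)), float(d), n)


def ld_expand(
    panel: HaplotypePanel,
    tag_variants: Iterable[str],
    threshold: float = 0.8,
) -> List[Tuple[str, Variant, LDResult]]:
    """All panel variants with r^2(tag, v) strictly above ``threshold``.

    The tag itself is always returned (r^2 = 1 with itself). Monomorphic
    panel sites are skipped (their LD with anything is undefined). Output is
    ordered by tag input order, then linked-variant position.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    out: List[Tuple[str, Variant, LDResult]] = []
    for tag in tag_variants:
        col = panel.column(tag)  # raises PanelLookupError naming the tag
        linked: List[Tuple[str, Variant, LDResult]] = []
        for v in panel.variants:
            if v.vid == tag:
                res = LDResult(tag, tag, 1.0, _self_d(panel, col), panel.n_haplotypes)
                linked.append((tag, v, res))
                continue
            try:
                res = r_squared(panel, tag, v.vid)
            except UndefinedLDError:
                continue
            if res.r2 > threshold:
                linked.append((tag, v, res))
        linked.sort(key=lambda t: (t[1].norm_chrom, t[1].pos))
        out.extend(linked)
    return out


def _self_d(panel: HaplotypePanel, col: int) -> float:
    p = float(panel.alleles[:, col].mean())
    return p * (1.0 - p)


def r_squared_se(maf_a: float, maf_b: float, r2: float, n_haplotypes: int) -> float:
    """Delta-method standard error of the r^2 estimate at the generating
    two-locus haplotype frequencies (positive-D parameterization).

    The sampling model is a multinomial over the four haplotypes; the
    gradient of r^2 with respect to the haplotype frequencies is evaluated
    numerically and propagated through the multinomial covariance.
    """
    d = np.sqrt(r2 * maf_a * (1 - maf_a) * maf_b * (1 - maf_b))
    p = np.array(
        [
            (1 - maf_a) * (1 - maf_b) + d,  # 00
            (1 - maf_a) * maf_b - d,        # 01
            maf_a * (1 - maf_b) - d,        # 10
            maf_a * maf_b + d,              # 11
        ]
    )
    if (p < -1e-12).any():
        raise ValueError(f"infeasible (maf, r2) combination: haplotype frequencies {p}")
    p = np.clip(p, 0.0, 1.0)

    def _r2_of(q: np.ndarray) -> float:
        q = q / q.sum()
        pa = q[2] + q[3]
        pb = q[1] + q[3]
        dd = q[3] - pa * pb
        return dd * dd / (pa * (1 - pa) * pb * (1 - pb))

    eps = 1e-6
    grad = np.zeros(4)
    for i in range(4):
        hi, lo = p.copy(), p.copy()
        hi[i] += eps
        lo[i] = max(lo[i] - eps, 0.0)
        grad[i] = (_r2_of(hi) - _r2_of(lo)) / (hi[i] - lo[i])
    cov = (np.diag(p) - np.outer(p, p)) / n_haplotypes
    var = float(grad @ cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# panel I/O (phased VCF subset)


def read_haplotype_panel(path: str, population: str = "") -> HaplotypePanel:
    """Load a phased VCF into a haplotype panel.

    Only the GT field is consumed. Multi-allelic records are rejected with an
    explicit error (pairwise LD here is defined for biallelic sites only).
    """
    from cyvcf2 import VCF

    variants: List[Variant] = []
    columns: List[np.ndarray] = []
    for i, rec in enumerate(VCF(str(path)), start=1):
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"{path}: record {i} ({rec.ID or rec.POS}): multi-allelic site not supported "
                f"for LD (ALT={rec.ALT})"
            )
        gts = np.array(rec.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=int).reshape(-1)
        if (alleles < 0).any():
            raise ValidationError(f"{path}: record {i}: missing genotype call")
        variants.append(
            Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], rec.ID or f"{rec.CHROM}:{rec.POS}")
        )
        columns.append(alleles.astype(np.uint8))
    if not columns:
        raise ValidationError(f"{path}: empty panel")
    return HaplotypePanel(
        alleles=np.stack(columns, axis=1), variants=variants, population=population
    )


def write_haplotype_panel(path: str, panel: HaplotypePanel) -> None:
    """Write the panel as a minimal phased VCF (GT only)."""
    n_samples = panel.n_haplotypes // 2
    order = sorted(range(panel.n_sites), key=lambda j: (panel.variants[j].norm_chrom, panel.variants[j].pos))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({v.chrom for v in panel.variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        samples = "\t".join(f"S{i}" for i in range(n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in order:
            v = panel.variants[j]
            col = panel.alleles[:, j]
            gts = "\t".join(f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(n_samples))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")
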