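"""Promoter windows, enhancer-promoter link joins, eQTL support, and
eRNA-based enhancer activity profiles.

Promoters are fixed-width windows strictly upstream of the TSS (the TSS base
itself is excluded). Enhancer-promoter links carry a cross-sample
correlation and per-cell-type normalized CAGE activity counts; a link's
activity profile expresses each cell type's share of the enhancer's total
eRNA output as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import pandas as pd

from .core.types import GeneModel, GenomicInterval, ValidationError, Variant


@dataclass(frozen=True)
class EPLink:
    """One enhancer-promoter pair: interval, target gene, correlation,
    per-cell-type activity (normalized CAGE counts)."""

    enhancer: GenomicInterval
    gene: str
    correlation: float
    activity: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 <= self.correlation <= 1.0):
            raise ValidationError(
                f"EP link {self.gene}: correlation {self.correlation} outside [-1, 1]"
            )
        if any(v < 0 for v in self.activity.values()):
            raise ValidationError(f"EP link {self.gene}: negative activity count")


@dataclass(frozen=True)
class ActivityProfile:
    """Percent-of-total eRNA expression per cell type for one enhancer."""

    enhancer: GenomicInterval
    percentages: Tuple[Tuple[str, float], ...]  # (cell type, percent), descending

    def top(self, n: int) -> Tuple[Tuple[str, float], ...]:
        return self.percentages[:n]


@dataclass(frozen=True)
class RegulatoryAssignment:
    """A variant assigned to a regulatory element and its target gene."""

    variant: Variant
    gene: str
    element: str  # "promoter" | "enhancer"
    interval: GenomicInterval
    transcript: str = ""
    link: Optional[EPLink] = None


def promoter_windows(genes: Sequence[GeneModel], width_bp: int = 2000) -> List[GenomicInterval]:
    """One window per transcript, ``width_bp`` strictly upstream of the TSS.

    Plus strand: [tss0 - width, tss0); minus strand: [tss0 + 1, tss0 + 1 + width)
    in 0-based half-open coordinates, so the TSS base itself is excluded on
    both strands. Windows running off the chromosome start are truncated at 0
    with a warning.
    """
    if width_bp <= 0:
        raise ValueError("width_bp must be > 0")
    out = []
    for g in genes:
        tss0 = g.tss - 1
        if g.strand == "+":
            start, end = tss0 - width_bp, tss0
        else:
            start, end = tss0 + 1, tss0 + 1 + width_bp
        if start < 0:
            warnings.warn(
                f"promoter window for {g.gene}/{g.transcript} truncated at position 0",
                stacklevel=2,
            )
            start = 0
        out.append(GenomicInterval(g.chrom, start, end, g.strand))
    return out


def map_promoter_variants(
    variants: Sequence[Variant],
    genes: Sequence[GeneModel],
    width_bp: int = 2000,
) -> List[RegulatoryAssignment]:
    """All (variant, promoter window) containments; a variant may map to
    several genes (no arbitration)."""
    windows = promoter_windows(genes, width_bp)
    out = []
    for v in variants:
        var_iv = GenomicInterval(v.chrom, v.pos0, v.pos0 + max(1, len(v.ref)))
        for w, g in zip(windows, genes):
            if var_iv.overlap_bp(w) >= 1:
                out.append(
                    RegulatoryAssignment(
                        variant=v,
                        gene=g.gene,
                        element="promoter",
                        interval=w,
                        transcript=g.transcript,
                    )
                )
    out.sort(key=lambda r: (r.variant.norm_chrom, r.variant.pos, r.gene, r.transcript))
    return out


def map_enhancer_variants(
    variants: Sequence[Variant],
    ep_links: Sequence[EPLink],
) -> List[RegulatoryAssignment]:
    """Containment of the variant position in a linked enhancer interval
    joins the link's target gene; multi-gene enhancers give one row per gene."""
    out = []
    for v in variants:
        for link in ep_links:
            if link.enhancer.contains_pos0(v.chrom, v.pos0):
                out.append(
                    RegulatoryAssignment(
                        variant=v,
                        gene=link.gene,
                        element="enhancer",
                        interval=link.enhancer,
                        link=link,
                    )
                )
    out.sort(key=lambda r: (r.variant.norm_chrom, r.variant.pos, r.gene))
    return out


def eqtl_support(
    assignments: Sequence[RegulatoryAssignment],
    eqtl_table: pd.DataFrame,
) -> Tuple[List[Tuple[RegulatoryAssignment, pd.DataFrame]], List[Tuple[RegulatoryAssignment, pd.DataFrame]]]:
    """Split assignments by eQTL support for the (variant, target gene) pair.

    Returns (supported, unsupported). A pair is supported when at least one
    *significant* association exists in any tissue; all matching records
    (significant or not) are attached for reporting, so support is always
    auditable from the input table.
    """
    supported, unsupported = [], []
    for a in assignments:
        records = eqtl_table[
            (eqtl_table["variant_id"] == a.variant.vid) & (eqtl_table["gene"] == a.gene)
        ]
        if bool(records["significant"].any()):
            supported.append((a, records))
        else:
            unsupported.append((a, records))
    return supported, unsupported


def enhancer_activity_percentages(link: EPLink) -> ActivityProfile:
    """Percentage of the enhancer's total eRNA output emitted per cell type.

    percentage_c = 100 * count_c / sum(counts); sorted descending, ties by
    cell-type name. All-zero activity is an error (no expression to apportion).
    """
    total = sum(link.activity.values())
    if total <= 0:
        raise ValidationError(
            f"enhancer {link.enhancer.chrom}:{link.enhancer.start}-{link.enhancer.end}: "
            "all-zero activity counts"
        )
    items = [(cell, 100.0 * count / total) for cell, count in link.activity.items()]
    items.sort(key=lambda t: (-t[1], t[0]))
    return ActivityProfile(enhancer=link.enhancer, percentages=tuple(items))
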