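"""Genomic-interval intersection under half-open arithmetic."""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Tuple

from .types import GenomicInterval, ValidationError


def _validated(intervals: Iterable[GenomicInterval], label: str) -> List[GenomicInterval]:
    out = []
    for i, iv in enumerate(intervals):
        if not isinstance(iv, GenomicInterval):
            raise ValidationError(f"{label}[{i}]: not a GenomicInterval: {iv!r}")
        out.append(iv)
    return out


def intersect_intervals(
    set_a: Iterable[GenomicInterval],
    set_b: Iterable[GenomicInterval],
) -> List[Tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs (a, b, overlap_bp) with overlap >= 1 bp.

    Half-open arithmetic: intervals sharing only a boundary do not overlap.
    Output is sorted by (chromosome, a.start, a.end, b.start, b.end), making
    the result deterministic regardless of input order. Chromosome names are
    compared with the ``chr`` prefix stripped.
    """
    a_list = _validated(set_a, "set_a")
    b_list = _validated(set_b, "set_b")

    by_chrom: Dict[str, List[GenomicInterval]] = defaultdict(list)
    for b in b_list:
        by_chrom[b.norm_chrom].append(b)
    for bs in by_chrom.values():
        bs.sort(key=lambda iv: (iv.start, iv.end))

    out: List[Tuple[GenomicInterval, GenomicInterval, int]] = []
    for a in a_list:
        for b in by_chrom.get(a.norm_chrom, ()):
            if b.start >= a.end:
                break  # b sorted by start: no later b can overlap a
            ov = a.overlap_bp(b)
            if ov >= 1:
                out.append((a, b, ov))
    out.sort(key=lambda t: (t[0].norm_chrom, t[0].start, t[0].end, t[1].start, t[1].end))
    return out
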