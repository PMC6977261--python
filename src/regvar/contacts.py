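"""Chromatin-contact evidence from binned Hi-C style matrices.

Observed/expected normalization divides each contact count by the mean count
at its genomic separation (per-diagonal mean, no smoothing). A virtual-4C
profile is the normalized anchor row; bins whose distance-normalized
frequency strictly exceeds the threshold (default 2) are called as contacts.
Same-TAD membership and convergent CTCF motif orientation at TAD boundaries
provide the structural corroboration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core.types import GenomicInterval, ValidationError, norm_chrom


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome.

    Bin ``i`` covers ``[i * bin_size, (i + 1) * bin_size)``.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n, m = self.counts.shape
        if n != m:
            raise ValidationError(f"contact matrix must be square, got {n} x {m}")
        if (self.counts < 0).any():
            raise ValidationError("contact matrix has negative entries")
        if not np.allclose(self.counts, self.counts.T):
            raise ValidationError("contact matrix must be symmetric")
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos0: int) -> int:
        b = pos0 // self.bin_size
        if not (0 <= b < self.n_bins):
            raise ValidationError(
                f"position {pos0} outside matrix span (0-{self.n_bins * self.bin_size})"
            )
        return b

    def bins_of_interval(self, interval: GenomicInterval) -> List[int]:
        if norm_chrom(interval.chrom) != norm_chrom(self.chrom) and self.chrom:
            raise ValidationError(
                f"anchor chromosome {interval.chrom} does not match matrix {self.chrom}"
            )
        lo = self.bin_of(interval.start)
        hi = self.bin_of(interval.end - 1)
        return list(range(lo, hi + 1))


@dataclass
class OEMatrix:
    """Observed/expected matrix with a per-diagonal validity mask."""

    values: np.ndarray
    expected: np.ndarray
    diag_mask: np.ndarray  # True where the diagonal had nonzero expected


@dataclass
class ContactProfile:
    """Virtual-4C output anchored at one locus."""

    anchor_bins: List[int]
    raw: np.ndarray
    normalized: np.ndarray
    calls: List[int]
    threshold: float


def expected_by_distance(matrix: ContactMatrix) -> np.ndarray:
    """Mean count over all bin pairs at each separation d = |i - j|."""
    counts = matrix.counts
    n = counts.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 bins")
    return np.array([float(np.mean(np.diagonal(counts, offset=d))) for d in range(n)])


def oe_normalize(matrix: ContactMatrix) -> OEMatrix:
    """Divide each entry by the mean at its separation.

    Diagonals with zero expected are masked and set to 0. On every unmasked
    diagonal the mean of the normalized values is exactly 1 by construction.
    """
    expected = expected_by_distance(matrix)
    n = matrix.n_bins
    i, j = np.indices((n, n))
    d = np.abs(i - j)
    mask = expected > 0
    exp_grid = expected[d]
    values = np.where(mask[d] & (exp_grid > 0), matrix.counts / np.where(exp_grid > 0, exp_grid, 1.0), 0.0)
    return OEMatrix(values=values, expected=expected, diag_mask=mask)


def virtual_4c(
    matrix: ContactMatrix,
    anchor: GenomicInterval,
    threshold: float = 2.0,
    oe: Optional[OEMatrix] = None,
) -> ContactProfile:
    """Anchor-row contact profile with strict > threshold contact calls.

    The profile averages the raw and normalized rows over all bins the anchor
    interval touches; anchor bins themselves are excluded from the calls.
    """
    anchor_bins = matrix.bins_of_interval(anchor)
    if oe is None:
        oe = oe_normalize(matrix)
    raw = matrix.counts[anchor_bins, :].mean(axis=0)
    normalized = oe.values[anchor_bins, :].mean(axis=0)
    calls = [
        b
        for b in range(matrix.n_bins)
        if b not in anchor_bins and normalized[b] > threshold
    ]
    return ContactProfile(
        anchor_bins=anchor_bins, raw=raw, normalized=normalized, calls=calls, threshold=threshold
    )


Locus = Union[int, GenomicInterval]


def _as_interval(chrom: str, locus: Locus) -> GenomicInterval:
    if isinstance(locus, GenomicInterval):
        return locus
    return GenomicInterval(chrom, locus, locus + 1)


def same_tad(tads: Sequence[GenomicInterval], locus_a: Locus, locus_b: Locus) -> bool:
    """True iff a single TAD interval entirely contains both loci.

    Point loci may be given as 0-based positions (taken on the TAD
    chromosome); a locus straddling a TAD boundary is not contained.
    """
    tads = sorted(tads, key=lambda t: (t.norm_chrom, t.start))
    for prev, cur in zip(tads, tads[1:]):
        if prev.norm_chrom == cur.norm_chrom and cur.start < prev.end:
            raise ValidationError("TAD intervals must be non-overlapping")
    for tad in tads:
        a = _as_interval(tad.chrom, locus_a)
        b = _as_interval(tad.chrom, locus_b)
        if tad.contains_interval(a) and tad.contains_interval(b):
            return True
    return False


@dataclass(frozen=True)
class MotifHit:
    """A strand-oriented motif occurrence (e.g. a CTCF site)."""

    interval: GenomicInterval
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError("motif hit strand must be + or -")


def convergent_ctcf(
    hits: Sequence[MotifHit],
    left_boundary: int,
    right_boundary: int,
    window_bp: int,
) -> Tuple[bool, str]:
    """Test convergent CTCF orientation at two TAD boundaries.

    True iff the best-scoring hit within ``window_bp`` of the left boundary
    is on the + strand and the best near the right boundary is on the -
    strand (motifs pointing toward each other). Ties break toward the hit
    nearest its boundary. Returns (flag, reason).
    """
    if not left_boundary < right_boundary:
        raise ValidationError("boundaries must satisfy left < right")

    def _best(boundary: int) -> Optional[MotifHit]:
        near = [
            h
            for h in hits
            if abs((h.interval.start + h.interval.end) // 2 - boundary) <= window_bp
        ]
        if not near:
            return None
        return min(
            near,
            key=lambda h: (
                -h.score,
                abs((h.interval.start + h.interval.end) // 2 - boundary),
                h.interval.start,
            ),
        )

    left = _best(left_boundary)
    if left is None:
        return False, f"no CTCF motif hit within {window_bp} bp of left boundary"
    right = _best(right_boundary)
    if right is None:
        return False, f"no CTCF motif hit within {window_bp} bp of right boundary"
    if left.strand == "+" and right.strand == "-":
        return True, "convergent orientation (+ at left boundary, - at right)"
    return False, f"non-convergent orientation ({left.strand} at left, {right.strand} at right)"
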