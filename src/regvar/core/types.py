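"""Core domain types shared by every pipeline stage.

Coordinate conventions: internal intervals are 0-based half-open (BED-like);
variant positions are 1-based (VCF-like) and converted only at interval
boundaries. Chromosome names are compared after stripping an optional ``chr``
prefix, since public sources mix ``chr1`` and ``1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_ALLELE_CHARS = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def norm_chrom(chrom: str) -> str:
    """Normalize a chromosome name by stripping an optional ``chr`` prefix."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Variant:
    """A sequence variant: 1-based position, explicit ref/alt allele strings.

    An empty ``ref`` denotes an insertion and an empty ``alt`` a deletion
    (the display convention ``G/-`` maps to ``alt == ""``).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vid: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"variant {self.vid!r}: empty chromosome")
        if self.pos < 1:
            raise ValidationError(f"variant {self.vid!r}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"variant {self.vid!r}: ref equals alt ({self.ref!r})")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not set(allele.upper()) <= _ALLELE_CHARS:
                raise ValidationError(
                    f"variant {self.vid!r}: {name} allele {allele!r} has non-ACGT characters"
                )

    @property
    def norm_chrom(self) -> str:
        return norm_chrom(self.chrom)

    @property
    def pos0(self) -> int:
        """0-based position of the first affected base."""
        return self.pos - 1

    def __str__(self) -> str:  # pragma: no cover - display helper
        ref = self.ref or "-"
        alt = self.alt or "-"
        return f"{self.chrom}:{self.pos}:{ref}>{alt}({self.vid})"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"interval strand must be +, - or '.', got {self.strand!r}")

    @property
    def norm_chrom(self) -> str:
        return norm_chrom(self.chrom)

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos0(self, chrom: str, pos0: int) -> bool:
        return norm_chrom(chrom) == self.norm_chrom and self.start <= pos0 < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            other.norm_chrom == self.norm_chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if other.norm_chrom != self.norm_chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """One transcript: gene symbol, 1-based TSS, strand, sorted exons.

    The TSS must coincide with the transcript 5' end: the start of the first
    exon on the plus strand, the end of the last exon on the minus strand.
    """

    gene: str
    tss: int
    strand: str
    transcript: str
    exons: tuple = field(default_factory=tuple)
    chrom_name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene}: strand must be + or -")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        if not self.chrom_name and exons:
            object.__setattr__(self, "chrom_name", exons[0].chrom)
        for prev, cur in zip(exons, exons[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"gene {self.gene} transcript {self.transcript}: exons overlap or unsorted"
                )
        if exons:
            tss0 = self.tss - 1
            five_prime = exons[0].start if self.strand == "+" else exons[-1].end - 1
            if tss0 != five_prime:
                raise ValidationError(
                    f"gene {self.gene} transcript {self.transcript}: TSS {self.tss} does not "
                    f"match transcript 5' end (expected 1-based {five_prime + 1})"
                )

    @property
    def chrom(self) -> str:
        if not self.chrom_name:
            raise ValidationError(f"gene {self.gene}: chromosome undefined (no exons given)")
        return self.chrom_name


@dataclass(frozen=True)
class GWASCatalogRecord:
    """One catalog association: tag SNP id, trait, p-value, study, risk allele."""

    marker: str
    trait: str
    pvalue: float
    study: str = ""
    risk_allele: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(
                f"marker {self.marker}: p-value must be in (0, 1], got {self.pvalue}"
            )
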