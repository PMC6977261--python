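"""Categorical deleteriousness rules for variants in gene regions.

The predictor outputs themselves (VEP consequence terms, PolyPhen-2
categories) are consumed as input annotations; only the decision rule is
applied here: frameshift, stop-gained and start-lost variants are candidates
outright, and missense variants are candidates when labeled probably or
possibly damaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import pandas as pd

from .core.types import FormatError

CONSEQUENCES = {
    "missense",
    "frameshift",
    "stop_gained",
    "start_lost",
    "synonymous",
    "splice_region",
    "other",
}
POLYPHEN_CATEGORIES = {"probably_damaging", "possibly_damaging", "benign", "unknown"}

_ALWAYS_DELETERIOUS = {"frameshift", "stop_gained", "start_lost"}
_DAMAGING = {"probably_damaging", "possibly_damaging"}


@dataclass(frozen=True)
class CodingAnnotation:
    """One (variant, transcript) annotation row."""

    variant_id: str
    gene: str
    consequence: str
    polyphen_category: str = "unknown"
    aa_change: str = ""

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise FormatError(
                f"variant {self.variant_id}: unknown consequence {self.consequence!r}"
            )
        if self.polyphen_category not in POLYPHEN_CATEGORIES:
            raise FormatError(
                f"variant {self.variant_id}: unknown PolyPhen category "
                f"{self.polyphen_category!r}"
            )


def classify_coding_variant(annotation: CodingAnnotation) -> Tuple[bool, str]:
    """Apply the deleteriousness rule to one annotation row.

    Returns ``(is_candidate, reason)``; the reason names the triggering rule.
    A pure function of the record: no cross-record state.
    """
    c = annotation.consequence
    if c in _ALWAYS_DELETERIOUS:
        return True, f"consequence {c} is deleterious per rule"
    if c == "missense":
        if annotation.polyphen_category in _DAMAGING:
            return True, f"missense labeled {annotation.polyphen_category}"
        if annotation.polyphen_category == "unknown":
            return False, "insufficient annotation (missense without PolyPhen category)"
        return False, f"missense labeled {annotation.polyphen_category} is not deleterious"
    return False, f"consequence {c} not in deleterious set"


def read_coding_annotations(path: str) -> List[CodingAnnotation]:
    """TSV columns: variant_id, gene, consequence, polyphen_category, aa_change."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"variant_id", "gene", "consequence"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for _, row in df.iterrows():
        out.append(
            CodingAnnotation(
                variant_id=row.variant_id,
                gene=row.gene,
                consequence=row.consequence,
                polyphen_category=row.get("polyphen_category", "") or "unknown",
                aa_change=row.get("aa_change", "") or "",
            )
        )
    return out


def write_coding_annotations(path: str, annotations: List[CodingAnnotation]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("variant_id\tgene\tconsequence\tpolyphen_category\taa_change\n")
        for a in annotations:
            fh.write(
                f"{a.variant_id}\t{a.gene}\t{a.consequence}\t{a.polyphen_category}\t{a.aa_change}\n"
            )
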