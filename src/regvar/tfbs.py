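"""PWM construction and allele-differential binding-site scoring.

A position frequency matrix (PFM, observed base counts per motif column) is
turned into a position weight matrix (PWM) of log2-odds against a background
distribution, with a pseudocount distributed by background. An allele effect
is the difference of best PWM scores between the two alleles of a variant,
restricted to scan windows that overlap the variant — so a stronger distal
hit cannot mask the local disruption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core.types import ValidationError, Variant, revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: 4 x width non-negative counts, rows A,C,G,T."""

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValidationError(f"motif {self.motif_id}: counts must be 4 x width")
        if counts.shape[1] < 4:
            raise ValidationError(f"motif {self.motif_id}: width must be >= 4")
        if (counts < 0).any():
            raise ValidationError(f"motif {self.motif_id}: negative counts")
        if (counts.sum(axis=0) <= 0).any():
            raise ValidationError(f"motif {self.motif_id}: zero column sums")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PWM:
    """Log2-odds matrix (bits) derived from a PFM."""

    motif_id: str
    name: str
    logodds: np.ndarray
    pseudocount: float
    background: np.ndarray

    @property
    def width(self) -> int:
        return self.logodds.shape[1]


@dataclass(frozen=True)
class AlleleEffect:
    """Allele-differential binding call for one (variant, motif) pair.

    ``delta = score_ref - score_alt`` in bits; ``call`` is ``loss`` when the
    alternate allele weakens the best overlapping site, ``gain`` when it
    strengthens it, ``neutral`` when |delta| does not exceed the threshold.
    """

    variant_id: str
    motif_id: str
    tf_name: str
    score_ref: float
    score_alt: float
    delta: float
    offset_ref: int
    strand_ref: str
    offset_alt: int
    strand_alt: str
    call: str


def pfm_to_pwm(
    pfm: PFM,
    pseudocount: float = 1.0,
    background: Optional[Sequence[float]] = None,
) -> PWM:
    """Log2-odds transform with a background-distributed pseudocount.

    entry(b, i) = log2( (count(b,i) + pc * bg_b) / (colsum_i + pc) / bg_b ).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities")
    bg = bg / bg.sum()
    colsum = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    logodds = np.log2(probs / bg[:, None])
    return PWM(pfm.motif_id, pfm.name, logodds, pseudocount, bg)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=int)
    except KeyError as e:
        raise ValidationError(f"non-ACGT base {e.args[0]!r} in sequence") from None


def _window_scores(pwm: PWM, seq: str) -> np.ndarray:
    """Forward-strand score of every window; shape (len(seq) - width + 1,)."""
    idx = _encode(seq)
    w = pwm.width
    n = len(idx) - w + 1
    cols = np.arange(w)
    return np.array([pwm.logodds[idx[o : o + w], cols].sum() for o in range(n)])


def scan_best(
    pwm: PWM,
    seq: str,
    both_strands: bool = True,
    offsets: Optional[Sequence[int]] = None,
) -> Tuple[float, int, str]:
    """Best log-odds window over the sequence (optionally both strands).

    Returns (score, offset, strand); offset indexes the forward sequence.
    Ties break toward the smallest offset, then the + strand. ``offsets``
    optionally restricts the scan to a subset of window offsets.
    """
    w = pwm.width
    if len(seq) < w:
        raise ValidationError(f"sequence length {len(seq)} shorter than motif width {w}")
    fwd = _window_scores(pwm, seq)
    candidates = [(float(fwd[o]), o, "+") for o in range(len(fwd))]
    if both_strands:
        rev = _window_scores(pwm, revcomp(seq))
        n = len(rev)
        # window at reverse offset o covers forward offset n - 1 - o
        candidates += [(float(rev[o]), n - 1 - o, "-") for o in range(n)]
    if offsets is not None:
        allowed = set(offsets)
        candidates = [c for c in candidates if c[1] in allowed]
        if not candidates:
            raise ValidationError("no scan window at the requested offsets")
    # max score; ties -> smallest offset, then '+' strand
    return max(candidates, key=lambda c: (c[0], -c[1], c[2] == "+"))


def allele_effect(
    pwm: PWM,
    context: str,
    variant: Variant,
    call_threshold: float = 0.0,
    both_strands: bool = True,
    center: Optional[int] = None,
) -> AlleleEffect:
    """Score both alleles over windows overlapping the variant and call the
    direction of the binding change.

    ``context`` is the reference-allele sequence; the variant base sits at
    ``center`` (default: the middle of the context). The context must extend
    at least width - 1 bases on each side of the variant. With the default
    ``call_threshold`` of 0 bits, ``neutral`` is reserved for exactly equal
    scores; any magnitude cutoff must be set explicitly.
    """
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        raise ValidationError(f"variant {variant.vid}: allele effects require a substitution")
    w = pwm.width
    c = len(context) // 2 if center is None else center
    if c < w - 1 or len(context) - c - 1 < w - 1:
        raise ValidationError(
            f"context too short: need >= {w - 1} bases each side of the variant, "
            f"have {c} left / {len(context) - c - 1} right"
        )
    if context[c].upper() != variant.ref.upper():
        raise ValidationError(
            f"variant {variant.vid}: context has {context[c]!r} at the variant "
            f"position, expected ref {variant.ref!r}"
        )
    alt_context = context[:c] + variant.alt.upper() + context[c + 1 :]
    overlapping = range(max(0, c - w + 1), min(len(context) - w, c) + 1)
    s_ref, o_ref, st_ref = scan_best(pwm, context, both_strands, offsets=overlapping)
    s_alt, o_alt, st_alt = scan_best(pwm, alt_context, both_strands, offsets=overlapping)
    delta = s_ref - s_alt
    if delta == 0.0 or abs(delta) < call_threshold:
        call = "neutral"
    elif delta > 0:
        call = "loss"
    else:
        call = "gain"
    return AlleleEffect(
        variant_id=variant.vid,
        motif_id=pwm.motif_id,
        tf_name=pwm.name,
        score_ref=float(s_ref),
        score_alt=float(s_alt),
        delta=float(delta),
        offset_ref=o_ref,
        strand_ref=st_ref,
        offset_alt=o_alt,
        strand_alt=st_alt,
        call=call,
    )
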