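"""Maximum-entropy splice-site models and the allele-delta deleteriousness rule.

The signal model is the maximum-entropy distribution over k-mers consistent
with a set of marginal constraints (low-order position-subset marginals of
observed splice sites), fitted by iterative proportional scaling over the
full 4^k table. A window is scored as log2 of the signal/null likelihood
ratio; an allele pair is called deleterious when the two scores differ by
strictly more than 5 (in absolute value).

Window geometry follows the standard donor/acceptor convention: the donor
window is a 9-mer of 3 exonic + 6 intronic bases and the acceptor window a
23-mer of 20 intronic + 3 exonic bases, on the coding strand.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core.types import GeneModel, ValidationError, Variant, revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_EXONIC, DONOR_INTRONIC = 3, 6       # 9-mer
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3  # 23-mer

DELTA_THRESHOLD = 5.0


class ConvergenceError(RuntimeError):
    """Iterative scaling failed to reproduce the constraints."""


@dataclass(frozen=True)
class MarginalConstraint:
    """Target marginal distribution over a subset of window positions.

    ``positions`` is a tuple of 0-based positions in [0, k); ``table`` is an
    array of shape (4,) * len(positions) over base tuples in A,C,G,T order,
    summing to 1.
    """

    positions: Tuple[int, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        tab = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", tab)
        if tab.shape != (4,) * len(self.positions):
            raise ValidationError(
                f"constraint on {self.positions}: table shape {tab.shape} "
                f"!= {(4,) * len(self.positions)}"
            )
        if (tab < 0).any() or abs(tab.sum() - 1.0) > 1e-9:
            raise ValidationError(f"constraint on {self.positions}: marginal must sum to 1")


@dataclass
class SpliceModel:
    """Signal distribution over 4^k k-mers plus a positional null model."""

    kind: str  # donor | acceptor | generic
    k: int
    signal: np.ndarray  # flat array of length 4**k, kmers in lexicographic ACGT order
    null: np.ndarray = field(default=None)  # (k, 4) per-position base probabilities

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (4**self.k,):
            raise ValidationError(f"signal must have length 4^{self.k}")
        if abs(self.signal.sum() - 1.0) > 1e-6:
            raise ValidationError("signal probabilities must sum to 1")
        if self.null is None:
            self.null = np.full((self.k, 4), 0.25)
        self.null = np.asarray(self.null, dtype=float)
        if self.null.shape != (self.k, 4):
            raise ValidationError(f"null must have shape ({self.k}, 4)")
        if not np.allclose(self.null.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("null probabilities must sum to 1 per position")

    def p_signal(self, seq: str) -> float:
        return float(self.signal[kmer_index(seq)])

    def p_null(self, seq: str) -> float:
        idx = [_BASE_INDEX[b] for b in seq]
        return float(np.prod(self.null[np.arange(self.k), idx]))

    # -- serialization (JSON, so published model tables can be supplied) ----

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "k": self.k,
                "signal": self.signal.tolist(),
                "null": self.null.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SpliceModel":
        obj = json.loads(text)
        return cls(
            kind=obj["kind"], k=int(obj["k"]),
            signal=np.array(obj["signal"]), null=np.array(obj["null"]),
        )


@dataclass(frozen=True)
class SpliceScore:
    sequence: str
    score: float  # log2(signal / null), bits


def kmer_index(seq: str) -> int:
    idx = 0
    for b in seq:
        try:
            idx = idx * 4 + _BASE_INDEX[b]
        except KeyError:
            raise ValidationError(f"non-ACGT base {b!r} in sequence {seq!r}") from None
    return idx


def all_kmers(k: int) -> List[str]:
    return ["".join(t) for t in itertools.product(BASES, repeat=k)]


def marginal_of(p: np.ndarray, k: int, positions: Sequence[int]) -> np.ndarray:
    """Marginal of a flat 4^k distribution over the given positions (in order)."""
    return _marginal_cube(np.asarray(p, dtype=float).reshape((4,) * k), tuple(positions))


def mem_fit(
    k: int,
    constraints: Iterable[MarginalConstraint],
    tol: float = 1e-10,
    max_iter: int = 500,
) -> SpliceModel:
    """Maximum-entropy distribution over 4^k k-mers matching all constraints.

    Fitted by iterative proportional scaling on the exhaustive table: starting
    from the uniform distribution, each constraint's current marginal is
    rescaled to its target in turn until every constraint is reproduced within
    ``tol``. Requires k <= 9 (exhaustive table).
    """
    if k > 9:
        raise ValueError("exhaustive fitting supports k <= 9")
    constraints = list(constraints)
    for c in constraints:
        if any(not (0 <= p < k) for p in c.positions):
            raise ValidationError(f"constraint positions {c.positions} outside [0, {k})")
    cube = np.full((4,) * k, 1.0 / 4**k)

    def _residual() -> float:
        worst = 0.0
        for c in constraints:
            cur = _marginal_cube(cube, c.positions)
            worst = max(worst, float(np.abs(cur - c.table).max()))
        return worst

    for _ in range(max_iter):
        for c in constraints:
            cur = _marginal_cube(cube, c.positions)
            ratio = np.where(cur > 0, c.table / np.where(cur > 0, cur, 1.0), 0.0)
            shape = [4 if i in c.positions else 1 for i in range(k)]
            # broadcast ratio over the untouched axes
            expand = ratio
            # move constraint axes into position order for broadcasting
            expand = np.transpose(expand, axes=np.argsort(c.positions)) if len(c.positions) > 1 else expand
            full = np.ones(shape)
            idx = [slice(None) if i in c.positions else 0 for i in range(k)]
            full[tuple(idx)] = expand
            cube = cube * full
            total = cube.sum()
            if total <= 0:
                raise ConvergenceError("distribution collapsed to zero mass (inconsistent constraints)")
            cube /= total
        if _residual() <= tol:
            return SpliceModel(kind="generic", k=k, signal=cube.reshape(-1))
    raise ConvergenceError(
        f"iterative scaling did not converge in {max_iter} iterations; "
        f"worst constraint residual {_residual():.3e}"
    )


def _marginal_cube(cube: np.ndarray, positions: Tuple[int, ...]) -> np.ndarray:
    k = cube.ndim
    other = tuple(i for i in range(k) if i not in positions)
    marg = cube.sum(axis=other) if other else cube.copy()
    if len(positions) > 1:
        # sum leaves axes in ascending position order; reorder to `positions`
        marg = np.transpose(marg, axes=np.argsort(np.argsort(positions)))
    return marg


def splice_score(model: SpliceModel, seq: str) -> SpliceScore:
    """log2(P_signal(seq) / P_null(seq)), in bits."""
    seq = seq.upper()
    if len(seq) != model.k:
        raise ValidationError(f"sequence length {len(seq)} != model window k={model.k}")
    p_sig = model.p_signal(seq)
    if p_sig <= 0.0:
        raise ValidationError(f"sequence {seq} has zero signal probability; score undefined")
    p_null = model.p_null(seq)
    if p_null <= 0.0:
        raise ValidationError(f"sequence {seq} has zero null probability; score undefined")
    return SpliceScore(sequence=seq, score=float(np.log2(p_sig / p_null)))


def splice_delta(
    model: SpliceModel,
    seq_protective: str,
    seq_risk: str,
    threshold: float = DELTA_THRESHOLD,
) -> Tuple[float, float, float, bool]:
    """Score both alleles' windows and apply the strict |delta| > 5 rule.

    Returns (score_protective, score_risk, delta, is_candidate) with
    delta = score_protective - score_risk. Direction (site gain vs loss) is
    carried by the sign of delta, not by candidacy.
    """
    if seq_protective.upper() == seq_risk.upper():
        raise ValidationError("alleles do not alter window: sequences identical")
    s_p = splice_score(model, seq_protective).score
    s_r = splice_score(model, seq_risk).score
    delta = s_p - s_r
    return s_p, s_r, delta, abs(delta) > threshold


# ---------------------------------------------------------------------------
# genomic windows


def donor_window(
    genome: Dict[str, str],
    transcript: GeneModel,
    boundary: int,
    variant: Optional[Variant] = None,
) -> Tuple[str, str]:
    """(ref, alt) donor 9-mers around an exon/intron boundary.

    ``boundary`` is the 0-based exclusive coordinate of the exon 3' end on
    the genome for plus-strand transcripts, or the 0-based exon start for
    minus-strand transcripts. The window covers 3 exonic + 6 intronic bases
    on the coding strand (reverse-complemented for minus strand). When a
    variant is given it must be a substitution inside the window; the alt
    window has it applied.
    """
    return _window(genome, transcript, boundary, variant, kind="donor")


def acceptor_window(
    genome: Dict[str, str],
    transcript: GeneModel,
    boundary: int,
    variant: Optional[Variant] = None,
) -> Tuple[str, str]:
    """(ref, alt) acceptor 23-mers: 20 intronic + 3 exonic bases."""
    return _window(genome, transcript, boundary, variant, kind="acceptor")


def _window(genome, transcript, boundary, variant, kind):
    from .core.io import fetch_sequence

    strand = transcript.strand
    if kind == "donor":
        if strand == "+":
            g_start, g_end = boundary - DONOR_EXONIC, boundary + DONOR_INTRONIC
        else:
            g_start, g_end = boundary - DONOR_INTRONIC, boundary + DONOR_EXONIC
    else:
        if strand == "+":
            g_start, g_end = boundary - ACCEPTOR_INTRONIC, boundary + ACCEPTOR_EXONIC
        else:
            g_start, g_end = boundary - ACCEPTOR_EXONIC, boundary + ACCEPTOR_INTRONIC
    chrom = transcript.chrom
    ref_fwd = fetch_sequence(genome, chrom, g_start, g_end).upper()
    alt_fwd = ref_fwd
    if variant is not None:
        if len(variant.ref) != 1 or len(variant.alt) != 1:
            raise ValidationError(
                f"variant {variant.vid}: only substitutions are supported in splice windows"
            )
        off = variant.pos0 - g_start
        if not (0 <= off < len(ref_fwd)):
            raise ValidationError(
                f"variant {variant.vid} at {variant.chrom}:{variant.pos} outside "
                f"window {chrom}:{g_start}-{g_end}"
            )
        if ref_fwd[off] != variant.ref.upper():
            raise ValidationError(
                f"variant {variant.vid}: genome has {ref_fwd[off]} at {variant.pos}, "
                f"expected ref {variant.ref}"
            )
        alt_fwd = ref_fwd[:off] + variant.alt.upper() + ref_fwd[off + 1 :]
    if strand == "-":
        return revcomp(ref_fwd), revcomp(alt_fwd)
    return ref_fwd, alt_fwd


def pwm_limit_model(k: int, marginals: np.ndarray, null: Optional[np.ndarray] = None) -> SpliceModel:
    """Closed-form independence model: product of per-position marginals."""
    marginals = np.asarray(marginals, dtype=float)
    cube = np.ones((4,) * k)
    for i in range(k):
        shape = [1] * k
        shape[i] = 4
        cube = cube * marginals[i].reshape(shape)
    return SpliceModel(kind="generic", k=k, signal=cube.reshape(-1), null=null)
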