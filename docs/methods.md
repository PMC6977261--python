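# Methods

`regvar` implements a post-GWAS variant-prioritization survey: starting from
trait-associated tag SNPs, it searches the surrounding haplotype for variants
with a plausible molecular mechanism — protein-damaging coding changes,
splice-site strength changes, or disruption of regulatory elements whose
target gene the variant measurably affects. This note describes the models
and decision rules, the tunable parameters, what the synthetic data emulate,
and the numerical choices.

## Pipeline model

The survey proceeds in two branches after a shared LD-expansion step:

1. **Trait filter.** GWAS-catalog records are kept when their trait string is
   in the configured trait list. p-values are carried as provenance only; no
   genome-wide-significance filter is applied, and no multiple-testing
   correction is performed anywhere in the pipeline (source-level
   significance — GTEx's eQTL calls, the peak caller's Q-values — is consumed
   as given).
2. **LD expansion.** For each tag SNP, every panel variant with r² strictly
   above the threshold (default 0.8) is retained, including the tag itself
   (r² = 1). r² = D²/(p_a q_a p_b q_b) with D = f₁₁ − p_a p_b, computed from
   phased haplotype frequencies. LD against a monomorphic site is an explicit
   error, never a silent 0, and multi-allelic sites are rejected — pairwise
   r² is defined here for biallelic sites only.
3. **Coding branch.** Consequence and PolyPhen-2 category labels are consumed
   as input. A variant is a candidate iff its consequence is frameshift,
   stop-gained or start-lost, or it is missense labeled probably/possibly
   damaging. Splice-window variants are candidates when the signal scores of
   the two alleles differ by strictly more than 5 bits (below).
4. **Regulatory branch.** Variants are assigned to promoters (fixed-width
   windows strictly upstream of each transcript's TSS, default 2 kb, TSS base
   excluded) and to enhancers (containment in an enhancer–promoter link's
   interval, which names the target gene). An assignment survives only if at
   least one *significant* eQTL record links the variant to that gene in any
   tissue, and at least one supplied motif shows a non-neutral allele effect.
   ChIP-seq peak overlap and chromatin-contact evidence are recorded as
   flags, not filters.

Candidates appearing under several transcripts are deduplicated per
(variant, gene, element); a variant appearing in several category tables is
counted once in the summary totals.

## Splice-site model

The signal model over k-mers is the maximum-entropy distribution consistent
with a set of marginal constraints (position subsets with target marginals),
fitted by iterative proportional scaling on the exhaustive 4^k table
(k ≤ 9). With only single-position constraints this reduces exactly to the
product-of-marginals (PWM) limit, which the tests verify to total-variation
< 1e-8. A window scores log₂(P_signal/P_null) bits, the null being a
per-position base-composition model (uniform by default). Window geometry is
the standard donor/acceptor convention: donor = 3 exonic + 6 intronic bases
(9-mer), acceptor = 20 intronic + 3 exonic (23-mer), reverse-complemented
for minus-strand transcripts. The published 5′/3′ model tables can be
supplied as a JSON `SpliceModel`; the test suite runs entirely on
exhaustively fitted toy models so no external download is required.

The deleteriousness rule is strict: |Δ| > 5 bits, where
Δ = score(protective) − score(risk). Direction (site gain vs loss) is
reported but does not affect candidacy; a pair exactly 5 bits apart is not a
candidate.

## TFBS disruption

A position frequency matrix is converted to log₂-odds with a pseudocount
(default 1.0) distributed by the background (default uniform):
entry(b,i) = log₂((count(b,i) + pc·bg_b)/(colsum_i + pc)/bg_b). Each allele's
context is scanned over both strands, restricted to windows overlapping the
variant so a stronger distal hit cannot mask the local change; ties break to
the smallest offset, then the + strand. The call is `loss` when the
alternate allele lowers the best overlapping score, `gain` when it raises
it; with the default 0-bit threshold `neutral` is reserved for exactly equal
scores, and any magnitude cutoff must be chosen explicitly (the upstream
tools this emulates do not publish theirs, so regenerated TF lists depend on
this choice).

## Chromatin-contact evidence

Contact matrices are normalized observed/expected with the expected model
being the plain per-diagonal mean (no smoothing, no iterative bias
correction — the "bias-removed" profile of browser tools is represented by
the input matrix as provided; this is a stated fidelity gap). A virtual-4C
profile is the normalized anchor row, averaged over the anchor's bins; bins
strictly above the threshold (default 2.0) are contact calls, anchor bins
excluded. Calls are invariant under global rescaling of the raw matrix by
construction. Same-TAD membership requires entire containment of both loci
in one TAD interval; a locus straddling a boundary is not contained.
Convergent CTCF orientation at a TAD requires the best-scoring motif hit
near the left boundary on + and near the right boundary on − (ties to the
hit nearest its boundary).

O/E values on shallow matrices are Poisson-noisy: at a per-cell mean of ~2
counts the normalized value exceeds 2 by chance routinely. The calibration
tests therefore run at coverage giving ≥ 20–50 expected counts per cell at
the tested separation, where a planted 3-fold loop is recovered in 100/100
seeded runs and a null matrix yields no spurious call in 100/100. Users of
real shallow Hi-C should treat >2 calls at low coverage with suspicion.

## Motif-partitioned peak comparison

Peaks are partitioned by exact substring containment of two same-length
8-mer forms (both strands by default): only-A, only-B, both (excluded from
testing), neither (tracked for audit). Signals are compared by Mann–Whitney
U from pooled midranks; the p-value is exact by enumeration when
min(n_a, n_b) ≤ 8 and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections is used, and the method
actually applied is reported. The continuity correction moves tail mass by
up to ~0.01 at n = 8, so exact and approximate p agree to ~0.015 there. At
α = 0.05 the test's null rejection rate over 10,000 simulated log-normal
signal pairs (n = 30 each) falls inside the binomial envelope
[0.043, 0.057].

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis assumes:

- **Haplotypes**: two-locus blocks drawn from the four-haplotype multinomial
  at target r², D taken positive (risk alleles co-occur) unless requested
  otherwise; blocks mutually independent. An unattainable (MAF, r²)
  combination raises an error stating the feasible maximum — note r² between
  sites with unequal allele frequencies is bounded below 1
  (D_max = min(q_a p_b, p_a q_b)).
- **Contact maps**: Poisson counts with mean
  depth·(|i−j|+1)^(−α)·τ^[same TAD]·λ^[loop pair]; defaults α = 1, τ = 1.5,
  λ = 4, depth 100, 10 kb bins.
- **Peaks**: log-normal signals with a log-scale shift δ favoring the
  protective motif form (defaults μ = 3, σ = 1, δ = 0.5); motifs are
  embedded by replacement into a uniform-ACGT background, with rejection
  sampling to keep the planted partition exact.
- **The locus fixture** ties these together: a gene at TSS 200,001 on a 1 Mb
  chromosome, an enhancer 170 kb downstream of the TSS carrying an
  AP-1-like TGAGTCAT motif whose last base the functional variant
  substitutes (T>C), a tag SNP at r² = 0.9832 with the functional variant
  at risk-allele frequency 0.2286 (n = 2000 haplotypes), a significant
  fibroblast eQTL with negative effect size (plus a non-significant liver
  record), an enhancer–promoter link with hepatocyte/fibroblast-dominated
  activity, a ChIP-seq peak over the motif, and a Hi-C loop joining the
  promoter and enhancer bins inside one TAD.

What the generators do **not** emulate: realistic allele-frequency spectra
and LD decay, GC/mappability biases in contact maps or peaks, correlated
eQTL effects across tissues, overlapping regulatory annotations. Passing
tests show the pipeline's logic is correct under its stated model, not that
the model captures every property of real data.

## Numerical and design choices

- Internal coordinates are 0-based half-open; VCF-style positions are
  1-based; conversion happens only at I/O boundaries. Chromosome names are
  compared with an optional `chr` prefix stripped.
- All threshold comparisons that gate candidacy are strict (r² > 0.8,
  |Δ| > 5, O/E > 2), matching the rules they implement; boundary values are
  excluded and tested.
- Iterative scaling converges when every constraint marginal is reproduced
  within `tol` (default 1e-10); non-convergence reports the worst residual.
  Inconsistent constraints that drive the distribution to zero mass raise
  immediately.
- Risk-allele orientation of a linked variant is inferred from the sign of D
  against the tag's risk haplotype; risk-allele frequency is computed from
  the panel (the column is panel-derived, not taken from the catalog).
- Determinism: identical configuration and inputs give byte-identical output
  files; generator outputs are byte-identical per seed.

## Problem sizes

The default test and acceptance runs use: 2000 haplotypes; a 1 Mb synthetic
chromosome at 10 kb bins (100-bin contact matrix); 150 + 150 peaks for the
signal comparison; 10,000 null replicates for test calibration; 100 seeded
runs for loop recovery. These sizes make every check reproducible on a
single CPU in minutes.

## Known limitations

- No iterative (ICE-style) bias correction of contact matrices.
- No EM estimator for unphased genotypes; the panel must be phased.
- Multi-allelic sites are excluded from LD, so HLA-class variation is
  invisible to the survey — a structural blind spot of the r²-based design.
- The TFBS call threshold that upstream motif-disruption services use is not
  public; TF lists are reproducible only relative to a chosen threshold.
- Conflicting transcript-level consequences are not arbitrated: each
  (variant, transcript) row is classified independently and all candidate
  rows are reported.
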