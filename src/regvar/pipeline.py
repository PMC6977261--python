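"""End-to-end orchestration: trait-filtered tag SNPs are LD-expanded, then
classified along a coding branch (categorical deleteriousness + splice-window
deltas) and a regulatory branch (promoter/enhancer assignment, eQTL support,
TFBS disruption, ChIP-seq peak confirmation, chromatin-contact evidence).

Each emitted candidate row carries its provenance chain: the tag marker, its
GWAS p-value and study, the r^2 linking tag and candidate, the target gene,
the affected TFs and the evidence flags. The run is deterministic given its
configuration; randomness only ever enters through synthetic input
generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import coding as coding_mod
from . import contacts as contacts_mod
from . import ld as ld_mod
from . import regulatory as reg_mod
from . import tfbs as tfbs_mod
from .core.types import GenomicInterval, GWASCatalogRecord, ValidationError, Variant
from .splice import SpliceModel, splice_delta
from .synthetic_data import LocusBundle

TABLE_COLUMNS = [
    "chrom",
    "position",
    "variant",
    "alleles_p_r",
    "raf",
    "gene",
    "aa_or_tf",
    "marker",
    "marker_p",
    "study",
    "r2",
]
EXTRA_COLUMNS = ["category", "eqtl_tissues", "peak_support", "contact_support"]


@dataclass
class PipelineConfig:
    """Run configuration; ``inputs`` maps input names to file paths."""

    traits: List[str]
    inputs: Dict[str, str]
    r2_threshold: float = 0.8
    promoter_width: int = 2000
    splice_delta_threshold: float = 5.0
    tfbs_call_threshold: float = 0.0
    contact_threshold: float = 2.0
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("r2_threshold", self.r2_threshold),
            ("promoter_width", self.promoter_width),
            ("splice_delta_threshold", self.splice_delta_threshold),
            ("contact_threshold", self.contact_threshold),
        ):
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh)
        base = Path(path).parent
        inputs = {k: str((base / v)) for k, v in obj.get("inputs", {}).items()}
        return cls(
            traits=list(obj["traits"]),
            inputs=inputs,
            r2_threshold=float(obj.get("r2_threshold", 0.8)),
            promoter_width=int(obj.get("promoter_width", 2000)),
            splice_delta_threshold=float(obj.get("splice_delta", 5.0)),
            tfbs_call_threshold=float(obj.get("tfbs_call_threshold", 0.0)),
            contact_threshold=float(obj.get("contact_threshold", 2.0)),
            output_dir=str(obj.get("output_dir", base / "out")),
            seed=int(obj.get("seed", 0)),
        )


@dataclass
class PipelineResult:
    exon_splice: pd.DataFrame
    promoter: pd.DataFrame
    enhancer: pd.DataFrame
    summary: Dict[str, int]
    audit: List[str] = field(default_factory=list)

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "exon_splice": self.exon_splice,
            "promoter": self.promoter,
            "enhancer": self.enhancer,
        }


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=TABLE_COLUMNS + EXTRA_COLUMNS)


def summarize_candidates(tables: Dict[str, pd.DataFrame]) -> Dict[str, int]:
    """Distinct-variant counts per category and overall.

    ``total`` counts distinct variant ids across all tables (a variant
    appearing in two categories counts once); ``noncoding`` counts distinct
    ids in the promoter and enhancer tables.
    """
    def _ids(name: str) -> set:
        df = tables.get(name)
        if df is None or df.empty:
            return set()
        return set(df["variant"].astype(str))

    exon_ids = _ids("exon_splice")
    prom_ids = _ids("promoter")
    enh_ids = _ids("enhancer")
    return {
        "total": len(exon_ids | prom_ids | enh_ids),
        "noncoding": len(prom_ids | enh_ids),
        "exon_splice": len(exon_ids),
        "promoter": len(prom_ids),
        "enhancer": len(enh_ids),
    }


# ---------------------------------------------------------------------------
# the run itself


def run_bundle(
    bundle: LocusBundle,
    traits: Sequence[str],
    r2_threshold: float = 0.8,
    promoter_width: int = 2000,
    splice_delta_threshold: float = 5.0,
    tfbs_call_threshold: float = 0.0,
    contact_threshold: float = 2.0,
    coding_annotations: Optional[Sequence[coding_mod.CodingAnnotation]] = None,
    splice_model: Optional[SpliceModel] = None,
    splice_windows: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Run the full survey on in-memory inputs.

    ``splice_windows`` rows need columns variant_id, gene, kind,
    seq_protective, seq_risk (allele windows on the coding strand).
    """
    audit: List[str] = []

    records = [r for r in bundle.gwas if r.trait in set(traits)]
    audit.append(f"trait filter: kept {len(records)}/{len(bundle.gwas)} catalog records")

    tags: List[GWASCatalogRecord] = []
    for r in records:
        if r.marker in bundle.panel.index:
            tags.append(r)
        else:
            audit.append(f"marker {r.marker} absent from haplotype panel; skipped")

    # LD expansion; keep, per linked variant, every (tag, r2) pair
    linked: Dict[str, Variant] = {}
    links: Dict[str, List[Tuple[GWASCatalogRecord, float]]] = {}
    for rec in tags:
        for tag_id, variant, res in ld_mod.ld_expand(bundle.panel, [rec.marker], r2_threshold):
            linked[variant.vid] = variant
            links.setdefault(variant.vid, []).append((rec, res.r2))
    audit.append(f"LD expansion: {len(linked)} variants above r^2 > {r2_threshold}")
    linked_variants = sorted(linked.values(), key=lambda v: (v.norm_chrom, v.pos))

    def _marker_fields(vid: str) -> Tuple[str, str, str, float]:
        pairs = sorted(links[vid], key=lambda t: -t[1])
        best = pairs[0]
        marker = ";".join(rec.marker for rec, _ in pairs)
        marker_p = ";".join(f"{rec.pvalue:.2E}" for rec, _ in pairs)
        study = ";".join(rec.study for rec, _ in pairs)
        return marker, marker_p, study, best[1]

    def _risk_orientation(v: Variant) -> Tuple[str, float]:
        """(alleles P/R display, risk allele frequency) from the panel.

        The risk allele of a linked variant is the allele positively
        associated with the tag's risk haplotype (sign of D); the panel is
        the frequency source.
        """
        col = bundle.panel.column(v.vid)
        alt_freq = float(bundle.panel.alleles[:, col].mean())
        best_rec = max(links[v.vid], key=lambda t: t[1])[0]
        try:
            res = ld_mod.r_squared(bundle.panel, best_rec.marker, v.vid)
            risk_is_alt = res.d >= 0
        except (ld_mod.UndefinedLDError, ld_mod.PanelLookupError):
            risk_is_alt = True
        if v.vid == best_rec.marker:
            risk_is_alt = (best_rec.risk_allele or v.alt) == v.alt
        if risk_is_alt:
            return f"{v.ref or '-'}/{v.alt or '-'}", alt_freq
        return f"{v.alt or '-'}/{v.ref or '-'}", 1.0 - alt_freq

    exon_rows: List[dict] = []
    promoter_rows: List[dict] = []
    enhancer_rows: List[dict] = []

    # ---- coding branch -----------------------------------------------------
    for ann in coding_annotations or []:
        if ann.variant_id not in linked:
            continue
        is_cand, reason = coding_mod.classify_coding_variant(ann)
        if not is_cand:
            audit.append(f"coding {ann.variant_id}: not a candidate ({reason})")
            continue
        v = linked[ann.variant_id]
        marker, marker_p, study, r2 = _marker_fields(v.vid)
        alleles, raf = _risk_orientation(v)
        exon_rows.append(
            dict(
                chrom=v.norm_chrom, position=v.pos, variant=v.vid, alleles_p_r=alleles,
                raf=round(raf, 4), gene=ann.gene, aa_or_tf=ann.aa_change, marker=marker,
                marker_p=marker_p, study=study, r2=round(r2, 4), category="exon",
                eqtl_tissues="", peak_support=False, contact_support=False,
            )
        )
        audit.append(f"coding {ann.variant_id}: candidate ({reason})")

    if splice_windows is not None and splice_model is not None:
        for _, row in splice_windows.iterrows():
            if row.variant_id not in linked:
                continue
            s_p, s_r, delta, is_cand = splice_delta(
                splice_model, row.seq_protective, row.seq_risk, splice_delta_threshold
            )
            if not is_cand:
                audit.append(
                    f"splice {row.variant_id}: |delta|={abs(delta):.3f} <= "
                    f"{splice_delta_threshold}, not a candidate"
                )
                continue
            v = linked[row.variant_id]
            marker, marker_p, study, r2 = _marker_fields(v.vid)
            alleles, raf = _risk_orientation(v)
            exon_rows.append(
                dict(
                    chrom=v.norm_chrom, position=v.pos, variant=v.vid, alleles_p_r=alleles,
                    raf=round(raf, 4), gene=row.gene,
                    aa_or_tf=f"{row.kind} site (delta={delta:.3f})",
                    marker=marker, marker_p=marker_p, study=study, r2=round(r2, 4),
                    category="splice", eqtl_tissues="", peak_support=False,
                    contact_support=False,
                )
            )

    # ---- regulatory branch -------------------------------------------------
    prom_assign = reg_mod.map_promoter_variants(linked_variants, bundle.genes, promoter_width)
    enh_assign = reg_mod.map_enhancer_variants(linked_variants, bundle.ep_links)
    supported, unsupported = reg_mod.eqtl_support(prom_assign + enh_assign, bundle.eqtl)
    for a, _ in unsupported:
        audit.append(
            f"{a.element} {a.variant.vid}->{a.gene}: no significant eQTL support, dropped"
        )

    pwms = [
        tfbs_mod.pfm_to_pwm(pfm) for pfm in bundle.pfms
    ]
    oe = contacts_mod.oe_normalize(bundle.matrix) if bundle.matrix is not None else None
    promoter_by_gene = {
        g.gene: w
        for g, w in zip(bundle.genes, reg_mod.promoter_windows(bundle.genes, promoter_width))
    }

    seen: set = set()
    for a, eqtl_records in supported:
        key = (a.variant.vid, a.gene, a.element)
        if key in seen:  # deduplicate (variant, gene) pairs across transcripts
            continue
        seen.add(key)
        v = a.variant

        affected = []
        for pwm in pwms:
            w = pwm.width
            lo, hi = v.pos0 - (w - 1), v.pos0 + w
            from .core.io import fetch_sequence

            context = fetch_sequence(bundle.genome, v.chrom, lo, hi)
            eff = tfbs_mod.allele_effect(pwm, context, v, tfbs_call_threshold)
            if eff.call != "neutral":
                affected.append(eff)
        if not affected:
            audit.append(f"{a.element} {v.vid}->{a.gene}: no TFBS affected, dropped")
            continue

        peak_support = any(p.interval.contains_pos0(v.chrom, v.pos0) for p in bundle.peaks)

        contact_support = False
        if bundle.matrix is not None and a.gene in promoter_by_gene:
            anchor = promoter_by_gene[a.gene]
            in_tad = contacts_mod.same_tad(
                bundle.tads, anchor, GenomicInterval(v.chrom, v.pos0, v.pos0 + 1)
            ) if bundle.tads else False
            profile = contacts_mod.virtual_4c(bundle.matrix, anchor, contact_threshold, oe)
            called = bundle.matrix.bin_of(v.pos0) in profile.calls
            contact_support = bool(in_tad and called)

        marker, marker_p, study, r2 = _marker_fields(v.vid)
        alleles, raf = _risk_orientation(v)
        tissues = ";".join(sorted(set(eqtl_records[eqtl_records.significant].tissue)))
        row = dict(
            chrom=v.norm_chrom, position=v.pos, variant=v.vid, alleles_p_r=alleles,
            raf=round(raf, 4), gene=a.gene,
            aa_or_tf=",".join(sorted({e.tf_name for e in affected})),
            marker=marker, marker_p=marker_p, study=study, r2=round(r2, 4),
            category=a.element, eqtl_tissues=tissues, peak_support=peak_support,
            contact_support=contact_support,
        )
        (promoter_rows if a.element == "promoter" else enhancer_rows).append(row)

    def _table(rows: List[dict]) -> pd.DataFrame:
        if not rows:
            return _empty_table()
        df = pd.DataFrame(rows, columns=TABLE_COLUMNS + EXTRA_COLUMNS)
        return df.sort_values(["chrom", "position", "variant", "gene"]).reset_index(drop=True)

    exon_splice = _table(exon_rows)
    promoter = _table(promoter_rows)
    enhancer = _table(enhancer_rows)
    result = PipelineResult(
        exon_splice=exon_splice,
        promoter=promoter,
        enhancer=enhancer,
        summary=summarize_candidates(
            {"exon_splice": exon_splice, "promoter": promoter, "enhancer": enhancer}
        ),
        audit=audit,
    )
    _audit_r2(result, r2_threshold)
    return result


def _audit_r2(result: PipelineResult, threshold: float) -> None:
    for name, df in result.tables().items():
        if df.empty:
            continue
        if not (df["r2"].astype(float) > threshold).all():
            raise ValidationError(f"table {name}: candidate with r^2 <= {threshold}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load all configured inputs from disk, run the survey, write outputs."""
    from . import ld
    from .core import io as cio

    inp = config.inputs

    def _need(name: str) -> str:
        if name not in inp:
            raise ValidationError(f"config inputs missing required entry {name!r}")
        if not Path(inp[name]).exists():
            raise ValidationError(f"input {name}: path {inp[name]} does not exist")
        return inp[name]

    bundle = LocusBundle(
        genome=cio.read_fasta(_need("genome")),
        genes=cio.read_gene_models(_need("genes")),
        panel=ld.read_haplotype_panel(_need("panel")),
        gwas=cio.read_gwas_catalog(_need("gwas")),
        ep_links=cio.read_ep_links(_need("ep_links")),
        eqtl=cio.read_eqtl_table(_need("eqtl")),
        pfms=cio.read_jaspar_pfms(_need("pfm")),
        peaks=cio.read_peaks(_need("peaks")),
        matrix=cio.read_contact_matrix(_need("matrix")) if "matrix" in inp else None,
        tads=cio.read_tads(_need("tads")) if "tads" in inp else [],
    )
    coding_annotations = (
        coding_mod.read_coding_annotations(inp["coding_annotations"])
        if "coding_annotations" in inp
        else None
    )
    splice_model = None
    splice_windows = None
    if "splice_model" in inp:
        splice_model = SpliceModel.from_json(Path(_need("splice_model")).read_text())
        if "splice_windows" in inp:
            splice_windows = pd.read_csv(_need("splice_windows"), sep="\t")

    result = run_bundle(
        bundle,
        traits=config.traits,
        r2_threshold=config.r2_threshold,
        promoter_width=config.promoter_width,
        splice_delta_threshold=config.splice_delta_threshold,
        tfbs_call_threshold=config.tfbs_call_threshold,
        contact_threshold=config.contact_threshold,
        coding_annotations=coding_annotations,
        splice_model=splice_model,
        splice_windows=splice_windows,
    )
    write_result(result, config.output_dir)
    return result


def write_result(result: PipelineResult, output_dir: str) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables().items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, lineterminator="\n")
    pd.Series(result.summary).to_csv(
        out / "summary.tsv", sep="\t", header=["count"], index_label="category",
        lineterminator="\n",
    )
    (out / "audit.log").write_text("\n".join(result.audit) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# curated reference candidate tables (shipped with the package)


def load_reference_tables() -> Dict[str, pd.DataFrame]:
    """The curated psoriasis candidate-variant tables shipped with the
    package: exon/splice, promoter and enhancer candidates with their tag
    markers, studies and r^2 values."""
    out = {}
    base = resources.files("regvar").joinpath("data/tables")
    for name in ("exon_splice", "promoter", "enhancer"):
        with base.joinpath(f"{name}_candidates.tsv").open(encoding="utf-8") as fh:
            out[name] = pd.read_csv(fh, sep="\t", dtype=str)
    return out
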