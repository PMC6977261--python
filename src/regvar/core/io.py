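"""Readers and writers for the plain-text formats the pipeline consumes.

All TSV writers emit a header line, tab delimiters, UTF-8 and LF endings.
Variant positions are 1-based on disk (VCF convention); intervals are 0-based
half-open (BED convention). Readers validate against the domain-type
invariants and raise :class:`FormatError`/:class:`ValidationError` naming the
offending record rather than silently coercing.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    FormatError,
    GeneModel,
    GenomicInterval,
    GWASCatalogRecord,
    ValidationError,
    Variant,
)

# ---------------------------------------------------------------------------
# variants


def read_variants(path: str, dialect: str = "vcf") -> List[Variant]:
    """Read variants from a VCF subset or a 5-column TSV.

    Multi-allelic rows are split into one :class:`Variant` per alternate
    allele. ``-`` (or ``.``) in a TSV allele column denotes the empty allele.
    """
    if dialect == "vcf":
        return _read_variants_vcf(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_vcf(path: str) -> List[Variant]:
    from cyvcf2 import VCF

    out: List[Variant] = []
    for i, rec in enumerate(VCF(str(path)), start=1):
        for alt in rec.ALT:
            try:
                out.append(
                    Variant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        vid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    )
                )
            except ValidationError as e:
                raise ValidationError(f"{path}: record {i}: {e}") from e
    return out


def _read_variants_tsv(path: str) -> List[Variant]:
    out: List[Variant] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["chrom", "pos", "id", "ref", "alt"]
        if header[:5] != required:
            raise FormatError(f"{path}: expected header columns {required}, got {header[:5]}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = fields[:5]
            ref = "" if ref in {"-", "."} else ref
            for one_alt in alt.split(","):
                one_alt = "" if one_alt in {"-", "."} else one_alt
                try:
                    out.append(Variant(chrom, int(pos), ref, one_alt, vid))
                except (ValidationError, ValueError) as e:
                    raise ValidationError(f"{path}: line {lineno}: {e}") from e
    return out


def write_variants(path: str, variants: Sequence[Variant], dialect: str = "vcf") -> None:
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("chrom\tpos\tid\tref\talt\n")
            for v in variants:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref or '-'}\t{v.alt or '-'}\n")
        return
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({v.chrom for v in variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.norm_chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> Dict[str, str]:
    """Whole-genome FASTA into a dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str, sequences: Dict[str, str], width: int = 70) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(genome: Dict[str, str], chrom: str, start: int, end: int) -> str:
    """0-based half-open slice, tolerant of a ``chr`` prefix mismatch."""
    from .types import norm_chrom

    if chrom in genome:
        seq = genome[chrom]
    else:
        by_norm = {norm_chrom(k): k for k in genome}
        key = by_norm.get(norm_chrom(chrom))
        if key is None:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = genome[key]
    if not (0 <= start < end <= len(seq)):
        raise ValidationError(f"slice {chrom}:{start}-{end} outside sequence of length {len(seq)}")
    return seq[start:end]


# ---------------------------------------------------------------------------
# JASPAR position frequency matrices

_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[?\s*([0-9.\s]*?)\s*\]?\s*$")


def read_jaspar_pfms(source: str) -> list:
    """Parse JASPAR 2016 text (``>ID NAME`` header, 4 bracketed count rows).

    ``source`` may be a path or the raw text itself. Returns a list of
    :class:`regvar.tfbs.PFM`.
    """
    from ..tfbs import PFM

    text = source
    p = Path(source)
    try:
        if p.exists():
            text = p.read_text(encoding="utf-8")
    except OSError:
        pass

    pfms: list = []
    header: Optional[str] = None
    rows: Dict[str, List[float]] = {}

    def _flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise FormatError(f"motif {header!r}: need exactly rows A, C, G, T, got {sorted(rows)}")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise FormatError(f"motif {header!r}: ragged count rows (widths {sorted(widths)})")
        parts = header.split(None, 1)
        motif_id = parts[0]
        name = parts[1] if len(parts) > 1 else motif_id
        counts = np.array([rows[b] for b in "ACGT"], dtype=float)
        pfms.append(PFM(motif_id=motif_id, name=name, counts=counts))
        header, rows = None, {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            header = line[1:].strip()
            continue
        m = _JASPAR_ROW.match(line)
        if m is None or header is None:
            raise FormatError(f"unparseable JASPAR line: {raw!r}")
        base, nums = m.group(1), m.group(2)
        if base in rows:
            raise FormatError(f"motif {header!r}: duplicate row for base {base}")
        rows[base] = [float(x) for x in nums.split()]
    _flush()
    return pfms


def write_jaspar_pfms(path: str, pfms: Sequence) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.name}\n")
            for b, row in zip("ACGT", pfm.counts):
                cells = " ".join(_fmt_num(x) for x in row)
                fh.write(f"{b} [ {cells} ]\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# contact matrices (dense or COO TSV)


def read_contact_matrix(path: str, bin_size: Optional[int] = None, chrom: str = ""):
    """Read a dense square table or COO triples into a ContactMatrix.

    The first line may be a ``# contact-matrix ...`` header recording format,
    chromosome and bin size (the writers emit one). A three-column body with
    header ``bin_i  bin_j  count`` is treated as COO; otherwise the body must
    be a dense square numeric table. The matrix is symmetrized as
    ``max(M[i,j], M[j,i])``; negative entries are rejected.
    """
    from ..contacts import ContactMatrix

    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    fmt = None
    if lines and lines[0].startswith("#"):
        meta = dict(
            kv.split("=", 1) for kv in lines[0].lstrip("# ").split() if "=" in kv
        )
        fmt = meta.get("format")
        chrom = meta.get("chrom", chrom)
        if "bin_size" in meta:
            bin_size = int(meta["bin_size"])
        lines = lines[1:]
    if bin_size is None:
        raise FormatError(f"{path}: bin_size missing (no header and no argument)")

    if fmt == "coo" or (lines and lines[0].split("\t")[:3] == ["bin_i", "bin_j", "count"]):
        if lines and lines[0].startswith("bin_i"):
            lines = lines[1:]
        triples = []
        for lineno, ln in enumerate(lines, start=1):
            parts = ln.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: COO line {lineno}: expected 3 columns")
            triples.append((int(parts[0]), int(parts[1]), float(parts[2])))
        n = 1 + max(max(i, j) for i, j, _ in triples) if triples else 0
        mat = np.zeros((n, n), dtype=float)
        for i, j, c in triples:
            if c < 0:
                raise FormatError(f"{path}: negative count at ({i},{j})")
            mat[i, j] = max(mat[i, j], c)
        mat = np.maximum(mat, mat.T)
        return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=mat)

    rows = [[float(x) for x in ln.split("\t")] for ln in lines]
    widths = {len(r) for r in rows}
    if len(widths) != 1 or widths != {len(rows)}:
        raise FormatError(f"{path}: dense matrix must be square, got {len(rows)} rows, widths {sorted(widths)}")
    mat = np.array(rows, dtype=float)
    if (mat < 0).any():
        raise FormatError(f"{path}: negative entries in dense matrix")
    mat = np.maximum(mat, mat.T)
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=mat)


def write_contact_matrix(path: str, matrix, fmt: str = "dense") -> None:
    header = f"# contact-matrix format={fmt} chrom={matrix.chrom} bin_size={matrix.bin_size}\n"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header)
        if fmt == "dense":
            for row in matrix.counts:
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")
        elif fmt == "coo":
            fh.write("bin_i\tbin_j\tcount\n")
            n = matrix.counts.shape[0]
            for i in range(n):
                for j in range(i, n):
                    c = matrix.counts[i, j]
                    if c != 0:
                        fh.write(f"{i}\t{j}\t{repr(float(c))}\n")
        else:
            raise ValueError(f"unknown contact matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str) -> List[GeneModel]:
    """TSV with columns gene, transcript, chrom, strand, tss (1-based),
    exon_starts, exon_ends (comma-separated, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "transcript", "chrom", "strand", "tss", "exon_starts", "exon_ends"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for _, row in df.iterrows():
        starts = [int(x) for x in str(row.exon_starts).split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x]
        if len(starts) != len(ends):
            raise FormatError(f"{path}: transcript {row.transcript}: exon start/end count mismatch")
        exons = tuple(
            GenomicInterval(row.chrom, s, e, row.strand) for s, e in zip(starts, ends)
        )
        out.append(
            GeneModel(
                gene=row.gene,
                tss=int(row.tss),
                strand=row.strand,
                transcript=row.transcript,
                exons=exons,
            )
        )
    return out


def write_gene_models(path: str, genes: Sequence[GeneModel]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\ttranscript\tchrom\tstrand\ttss\texon_starts\texon_ends\n")
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons)
            ends = ",".join(str(e.end) for e in g.exons)
            fh.write(f"{g.gene}\t{g.transcript}\t{g.chrom}\t{g.strand}\t{g.tss}\t{starts}\t{ends}\n")


# ---------------------------------------------------------------------------
# GWAS catalog / eQTL / enhancer-promoter link tables


def read_gwas_catalog(path: str) -> List[GWASCatalogRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker", "trait", "pvalue"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                GWASCatalogRecord(
                    marker=row.marker,
                    trait=row.trait,
                    pvalue=float(row.pvalue),
                    study=row.get("study", "") or "",
                    risk_allele=row.get("risk_allele", "") or "",
                )
            )
        except (ValidationError, ValueError) as e:
            raise ValidationError(f"{path}: row {i + 2}: {e}") from e
    return out


def write_gwas_catalog(path: str, records: Sequence[GWASCatalogRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("marker\ttrait\tpvalue\tstudy\trisk_allele\n")
        for r in records:
            fh.write(f"{r.marker}\t{r.trait}\t{r.pvalue!r}\t{r.study}\t{r.risk_allele}\n")


def read_eqtl_table(path: str) -> pd.DataFrame:
    """GTEx-style associations: variant_id, gene, tissue, nes, significant."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene", "tissue", "nes", "significant"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    df["significant"] = df["significant"].astype(bool)
    df["nes"] = df["nes"].astype(float)
    return df


def write_eqtl_table(path: str, df: pd.DataFrame) -> None:
    df = df.copy()
    df["significant"] = df["significant"].astype(bool)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ep_links(path: str) -> list:
    """Enhancer-promoter link TSV: enh_chrom, enh_start, enh_end, gene,
    correlation, then one normalized-CAGE activity column per cell type."""
    from ..regulatory import EPLink

    df = pd.read_csv(path, sep="\t")
    fixed = ["enh_chrom", "enh_start", "enh_end", "gene", "correlation"]
    if list(df.columns[:5]) != fixed:
        raise FormatError(f"{path}: expected leading columns {fixed}, got {list(df.columns[:5])}")
    cell_types = list(df.columns[5:])
    out = []
    for _, row in df.iterrows():
        activity = {c: float(row[c]) for c in cell_types}
        out.append(
            EPLink(
                enhancer=GenomicInterval(row.enh_chrom, int(row.enh_start), int(row.enh_end)),
                gene=row.gene,
                correlation=float(row.correlation),
                activity=activity,
            )
        )
    return out


def write_ep_links(path: str, links: Sequence) -> None:
    cell_types = sorted({c for ln in links for c in ln.activity})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("enh_chrom\tenh_start\tenh_end\tgene\tcorrelation\t" + "\t".join(cell_types) + "\n")
        for ln in links:
            acts = "\t".join(repr(float(ln.activity.get(c, 0.0))) for c in cell_types)
            fh.write(
                f"{ln.enhancer.chrom}\t{ln.enhancer.start}\t{ln.enhancer.end}\t"
                f"{ln.gene}\t{ln.correlation!r}\t{acts}\n"
            )


# ---------------------------------------------------------------------------
# peaks and TADs (BED-like)


def read_peaks(path: str) -> list:
    """BED3 + name + numeric signal column (cols: chrom start end name signal)."""
    from ..peak_stats import Peak

    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: expected >= 4 columns")
            signal_str = parts[4] if len(parts) >= 5 else parts[3]
            try:
                signal = float(signal_str)
            except ValueError as e:
                raise FormatError(f"{path}: line {lineno}: non-numeric signal {signal_str!r}") from e
            out.append(
                Peak(
                    interval=GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                    signal=signal,
                    name=parts[3] if len(parts) >= 5 else f"peak_{lineno}",
                )
            )
    return out


def write_peaks(path: str, peaks: Sequence) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#chrom\tstart\tend\tname\tsignal\n")
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.name}\t{p.signal!r}\n"
            )


def read_tads(path: str) -> List[GenomicInterval]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected BED3")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_tads(path: str, tads: Sequence[GenomicInterval]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#chrom\tstart\tend\n")
        for t in tads:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")
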