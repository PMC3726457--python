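"""Readers and writers for every file format the triage pipeline touches.

All genomic coordinates in files follow the same 1-based inclusive convention
as the in-memory types, with one exception: BED12 input uses the standard
0-based half-open BED convention and is converted on the way in.

Tabular sidecars are TSV with a header row.  Writers are deterministic
(stable column order, fixed float formatting) so that write -> read -> write
round-trips are byte-identical, which the pipeline relies on for its
self-audit of archived intermediates.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    AnnotationFeature,
    AnnotationSet,
    ExpressionRow,
    GenomicInterval,
    HomologyHit,
    ParseError,
    TranscriptModel,
)

# ---------------------------------------------------------------------------
# small helpers


def _open(source, mode: str = "r"):
    """Accept a path or an open text handle; returns (handle, should_close)."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def _name(source) -> str:
    if isinstance(source, (str, Path)):
        return str(source)
    return getattr(source, "name", "<stream>")


def _fmt_depth(x: float) -> str:
    return f"{x:g}"


# ---------------------------------------------------------------------------
# GTF attribute handling (both GTF `key "value";` and GFF3 `key=value` styles)


def parse_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    field = field.strip()
    if "=" in field and '"' not in field:  # GFF3 dialect
        for part in field.split(";"):
            part = part.strip()
            if part and "=" in part:
                k, v = part.split("=", 1)
                attrs[k.strip()] = v.strip()
        return attrs
    for part in field.split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            k, v = part.split(" ", 1)
            attrs[k.strip()] = v.strip().strip('"')
    return attrs


# ---------------------------------------------------------------------------
# transcript models: GTF (exon records keyed by transcript_id) and BED12


def read_models_gtf(source) -> dict[str, list[GenomicInterval]]:
    """Collect exon intervals per transcript_id from a GTF-dialect stream."""
    handle, close = _open(source)
    exons: dict[str, list[GenomicInterval]] = {}
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(parts)}",
                    _name(source), lineno,
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attr = parts
            if feature != "exon":
                continue
            attrs = parse_attributes(attr)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError("exon record without transcript_id", _name(source), lineno)
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand if strand in "+-" else ".")
            except ValueError as exc:
                raise ParseError(str(exc), _name(source), lineno) from exc
            prior = exons.setdefault(tid, [])
            if prior and prior[0].chrom != chrom:
                raise ParseError(
                    f"transcript {tid} has exons on {prior[0].chrom} and {chrom}",
                    _name(source), lineno,
                )
            prior.append(iv)
    finally:
        if close:
            handle.close()
    return exons


def read_models_bed12(source) -> dict[str, list[GenomicInterval]]:
    """Collect exon intervals per model from BED12 (0-based half-open input)."""
    handle, close = _open(source)
    exons: dict[str, list[GenomicInterval]] = {}
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(
                    f"expected >= 12 BED12 fields, got {len(parts)}", _name(source), lineno
                )
            chrom, chrom_start, _end, name, _score, strand = parts[:6]
            block_count = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(f"malformed blocks for {name}", _name(source), lineno)
            if name in exons:
                raise ParseError(f"duplicate BED12 name {name}", _name(source), lineno)
            base = int(chrom_start)
            exons[name] = [
                GenomicInterval(
                    chrom, base + off + 1, base + off + size,
                    strand if strand in "+-" else ".",
                )
                for off, size in zip(starts, sizes)
            ]
    finally:
        if close:
            handle.close()
    return exons


def read_evidence_tsv(source) -> dict[str, tuple[float, list[int]]]:
    """Depth / junction-read sidecar: transcript_id, depth, junction_reads.

    ``junction_reads`` is a comma-separated list of spanning-read counts, one
    per intron in genomic order; it may be empty for single-exon models.
    """
    handle, close = _open(source)
    out: dict[str, tuple[float, list[int]]] = {}
    try:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["transcript_id", "depth"]:
            raise ParseError(
                f"unexpected evidence header {header!r}", _name(source), 1
            )
        for lineno, line in enumerate(handle, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            tid, depth = parts[0], float(parts[1])
            counts: list[int] = []
            if len(parts) > 2 and parts[2]:
                counts = [int(x) for x in parts[2].split(",")]
            out[tid] = (depth, counts)
    finally:
        if close:
            handle.close()
    return out


def read_transcript_models(model_source, evidence_source=None) -> list[TranscriptModel]:
    """Assemble :class:`TranscriptModel` objects from a model file + sidecar.

    The model file may be GTF-dialect (exon features carrying
    ``transcript_id``) or BED12; the dialect is sniffed from the first data
    line.  Models missing from the evidence sidecar get depth 0.
    """
    handle, close = _open(model_source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    first = next(
        (l for l in text.splitlines() if l.strip() and not l.startswith(("#", "track", "browser"))),
        "",
    )
    fields = first.split("\t")
    is_gtf = len(fields) == 9 and fields[2] and not fields[2].isdigit()
    reader = read_models_gtf if is_gtf else read_models_bed12
    exons_by_id = reader(_io.StringIO(text))

    evidence: dict[str, tuple[float, list[int]]] = {}
    if evidence_source is not None:
        evidence = read_evidence_tsv(evidence_source)

    models = []
    for tid, exons in exons_by_id.items():
        depth, counts = evidence.get(tid, (0.0, []))
        model = TranscriptModel(tid, exons, depth=depth)
        introns = model.introns
        if counts and len(counts) == len(introns):
            model.junction_support = list(zip(introns, counts))
        models.append(model)
    return models


def write_models_gtf(models: Sequence[TranscriptModel], dest, source_tag: str = "novtx") -> None:
    handle, close = _open(dest, "w")
    try:
        for m in models:
            for i, exon in enumerate(m.exons, 1):
                attrs = f'transcript_id "{m.id}"; exon_number "{i}";'
                handle.write(
                    f"{exon.chrom}\t{source_tag}\texon\t{exon.start}\t{exon.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
    finally:
        if close:
            handle.close()


def write_evidence_tsv(models: Sequence[TranscriptModel], dest) -> None:
    handle, close = _open(dest, "w")
    try:
        handle.write("transcript_id\tdepth\tjunction_reads\n")
        for m in models:
            counts = ",".join(str(c) for _iv, c in m.junction_support)
            handle.write(f"{m.id}\t{_fmt_depth(m.depth)}\t{counts}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# reference annotation (GTF/GFF3 gene + pseudogene features)

_GENE_FEATURES = {"gene", "pseudogene"}


def read_annotation(source, feature_types: set[str] | None = None) -> AnnotationSet:
    feature_types = feature_types or _GENE_FEATURES
    handle, close = _open(source)
    ann = AnnotationSet()
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(
                    f"expected 9 fields, got {len(parts)}", _name(source), lineno
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attr = parts
            if feature not in feature_types:
                continue
            attrs = parse_attributes(attr)
            fid = attrs.get("gene_id") or attrs.get("ID")
            if fid is None:
                raise ParseError("gene record without gene_id/ID", _name(source), lineno)
            biotype = attrs.get("gene_biotype") or attrs.get("biotype") or (
                "pseudogene" if feature == "pseudogene" else "protein_coding"
            )
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand if strand in "+-" else ".")
            except ValueError as exc:
                raise ParseError(str(exc), _name(source), lineno) from exc
            ann.add(AnnotationFeature(fid, iv, biotype))
    finally:
        if close:
            handle.close()
    return ann


def write_annotation(ann: AnnotationSet, dest, source_tag: str = "novtx") -> None:
    handle, close = _open(dest, "w")
    try:
        for feat in sorted(ann, key=lambda f: (f.interval.chrom, f.interval.start, f.id)):
            iv = feat.interval
            feature = "pseudogene" if feat.biotype == "pseudogene" else "gene"
            attrs = f'gene_id "{feat.id}"; gene_biotype "{feat.biotype}";'
            handle.write(
                f"{iv.chrom}\t{source_tag}\t{feature}\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# expression matrix (transcripts x tissues)


def read_expression_tsv(source) -> list[ExpressionRow]:
    df = pd.read_csv(source, sep="\t", dtype={"transcript_id": str})
    if df.columns[0] != "transcript_id":
        raise ParseError(f"first expression column must be transcript_id, got {df.columns[0]!r}",
                         _name(source))
    tissues = list(df.columns[1:])
    return [
        ExpressionRow(row[0], [float(v) for v in row[1:]], tissues)
        for row in df.itertuples(index=False)
    ]


def write_expression_tsv(rows: Sequence[ExpressionRow], dest) -> None:
    if not rows:
        handle, close = _open(dest, "w")
        try:
            handle.write("transcript_id\n")
        finally:
            if close:
                handle.close()
        return
    tissues = rows[0].tissue_names
    handle, close = _open(dest, "w")
    try:
        handle.write("transcript_id\t" + "\t".join(tissues) + "\n")
        for r in rows:
            if r.tissue_names != tissues:
                raise ValueError(f"{r.transcript_id}: inconsistent tissue names")
            handle.write(r.transcript_id + "\t" + "\t".join(f"{v:.6g}" for v in r.values) + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# homology hit tables: BLAST 12-column tabular + 2 extension columns

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "subject_description", "is_annotated",
]


def read_homology_tsv(source) -> list[HomologyHit]:
    df = pd.read_csv(source, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"hit table missing columns {sorted(missing)}", _name(source))
    return [
        HomologyHit(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
            subject_is_annotated_gene=bool(int(r.is_annotated)),
            subject_description=str(r.subject_description),
        )
        for r in df.itertuples(index=False)
    ]


def write_homology_tsv(rows: pd.DataFrame, dest) -> None:
    rows.to_csv(dest, sep="\t", index=False, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# ortholog tables and alignment blocks

ORTHOLOG_COLUMNS = [
    "source_gene", "species", "target_gene",
    "target_chrom", "target_start", "target_end", "target_strand",
]

BLOCK_COLUMNS = ["species", "chrom", "start", "end"]


def read_orthologs_tsv(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype={"target_chrom": str, "target_gene": str})
    missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"ortholog table missing columns {sorted(missing)}", _name(source))
    return df


def write_orthologs_tsv(df: pd.DataFrame, dest) -> None:
    df.to_csv(dest, sep="\t", index=False, columns=ORTHOLOG_COLUMNS)


def read_blocks_tsv(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    missing = set(BLOCK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"block table missing columns {sorted(missing)}", _name(source))
    return df


def write_blocks_tsv(df: pd.DataFrame, dest) -> None:
    df.to_csv(dest, sep="\t", index=False, columns=BLOCK_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], dest, width: int = 80) -> None:
    handle, close = _open(dest, "w")
    try:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width])
                handle.write("\n")
    finally:
        if close:
            handle.close()


def read_fasta(source) -> dict[str, str]:
    """Load an entire (small) FASTA into memory.  For random access to large
    genomes use :class:`pyfaidx.Fasta` directly; every function in this
    package that takes a genome accepts either."""
    handle, close = _open(source)
    out: dict[str, list[str]] = {}
    name = None
    try:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif name is not None and line:
                out[name].append(line)
    finally:
        if close:
            handle.close()
    return {k: "".join(v) for k, v in out.items()}
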