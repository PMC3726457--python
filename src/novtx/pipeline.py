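"""End-to-end orchestration: novelty screen -> cascade -> ORF filter ->
homology triage -> optional primer/PCR validation -> optional synteny
contexts.

Stages communicate through files (TSV/GTF/FASTA) so each is independently
re-runnable, mirroring a chained-tool analysis.  Every count in the final
report can be recomputed from the archived intermediates, and a rerun with
an identical config produces a byte-identical report (the provenance block
carries the config hash and package version; wall-clock timestamps go to the
log only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import io as nio
from .core import AnnotationSet, NovtxError, TranscriptModel, overlaps_annotation
from .homology import classify_homology, summarize_homology
from .orfs import extract_spliced_sequence, longest_orf_length
from .prioritize import CascadeReport, FilterConfig, run_cascade
from .primers import (
    PrimerPair,
    ThermoParams,
    amplicon_spans_all_exons,
    assess_specificity,
    check_primer_constraints,
    insilico_pcr,
)
from .synteny import (
    alignment_coverage_percent,
    attach_blocks,
    attach_orthologs,
    build_context,
    conserved_synteny_fraction,
    detect_inversion,
    gene_order_tau,
)

logger = logging.getLogger(__name__)


class StageError(NovtxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage}: {message}")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    models: str
    evidence: str
    annotation: str
    expression: str
    genome: str | None = None
    hits: str | None = None
    primers: str | None = None
    orthologs: str | None = None
    blocks: str | None = None
    outdir: str = "novtx_out"
    filters: FilterConfig = field(default_factory=FilterConfig)
    min_orf_aa: int = 50
    evalue_max: float = 1e-5
    bitscore_min: float = 100.0
    thermo: ThermoParams = field(default_factory=ThermoParams)
    synteny_span: int = 1_000_000
    synteny_species: tuple[str, ...] = ("human", "dog", "cattle")
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if isinstance(data.get("filters"), dict):
            data["filters"] = FilterConfig(**data["filters"])
        if isinstance(data.get("thermo"), dict):
            data["thermo"] = ThermoParams(**data["thermo"])
        if isinstance(data.get("synteny_species"), list):
            data["synteny_species"] = tuple(data["synteny_species"])
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    code: str
    message: str


def validate_inputs(config: RunConfig) -> list[Finding]:
    """Machine-readable schema/coordinate findings; errors block a run."""
    findings: list[Finding] = []
    for attr in ("models", "evidence", "annotation", "expression"):
        path = getattr(config, attr)
        if path is None or not Path(path).exists():
            findings.append(Finding("error", "missing_input", f"{attr} file not found: {path}"))
    for attr in ("genome", "hits", "primers", "orthologs", "blocks"):
        path = getattr(config, attr)
        if path is not None and not Path(path).exists():
            findings.append(Finding("error", "missing_input", f"{attr} file not found: {path}"))
    if any(f.level == "error" for f in findings):
        return findings

    try:
        models = nio.read_transcript_models(config.models, config.evidence)
    except (NovtxError, ValueError) as exc:
        return findings + [Finding("error", "malformed_models", str(exc))]
    try:
        nio.read_annotation(config.annotation)
    except (NovtxError, ValueError) as exc:
        findings.append(Finding("error", "malformed_annotation", str(exc)))
    try:
        expr = nio.read_expression_tsv(config.expression)
    except (NovtxError, ValueError) as exc:
        return findings + [Finding("error", "malformed_expression", str(exc))]

    expr_ids = {r.transcript_id for r in expr}
    for m in models:
        if m.id not in expr_ids:
            findings.append(
                Finding("warning", "missing_expression",
                        f"transcript {m.id} has no expression row")
            )
    if config.genome is not None:
        import pyfaidx

        try:
            genome = pyfaidx.Fasta(config.genome)
            lengths = {name: len(genome[name]) for name in genome.keys()}
            for m in models:
                if m.chrom not in lengths:
                    findings.append(
                        Finding("error", "unknown_chromosome",
                                f"transcript {m.id} on {m.chrom} absent from genome")
                    )
                elif m.span.end > lengths[m.chrom]:
                    findings.append(
                        Finding("error", "coordinate_overflow",
                                f"transcript {m.id} exceeds {m.chrom} length")
                    )
        except Exception as exc:  # malformed FASTA
            findings.append(Finding("error", "malformed_genome", str(exc)))
    return findings


@dataclass
class RunReport:
    """Counts and per-candidate verdicts of one full run."""

    input_count: int = 0
    novel_count: int = 0
    cascade: CascadeReport | None = None
    orf_pass_count: int = 0
    candidate_ids: list[str] = field(default_factory=list)
    homology_summary: dict | None = None
    pcr: list[dict] = field(default_factory=list)
    synteny: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "input_count": self.input_count,
            "novel_count": self.novel_count,
            "orf_pass_count": self.orf_pass_count,
            "candidate_ids": sorted(self.candidate_ids),
            "homology_summary": self.homology_summary,
            "pcr": self.pcr,
            "synteny": self.synteny,
            "provenance": self.provenance,
        }
        if self.cascade is not None:
            out["cascade"] = {
                "stages": self.cascade.stage_names,
                "counts_after_stage": self.cascade.counts_after_stage,
            }
        return out


def _write_id_list(ids, path: Path) -> None:
    path.write_text("transcript_id\n" + "".join(f"{i}\n" for i in sorted(ids)))


def run_full(config: RunConfig) -> RunReport:
    """Execute the whole triage workflow and archive all intermediates."""
    findings = validate_inputs(config)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise StageError("validate", "; ".join(f.message for f in errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "run_config.json")

    # --- load
    try:
        models = nio.read_transcript_models(config.models, config.evidence)
        ann = nio.read_annotation(config.annotation)
        expression = nio.read_expression_tsv(config.expression)
    except (NovtxError, ValueError) as exc:
        raise StageError("load", str(exc)) from exc

    report = RunReport(input_count=len(models))

    # --- novelty screen
    novel = [m for m in models if not overlaps_annotation(m, ann)]
    report.novel_count = len(novel)
    _write_id_list([m.id for m in novel], outdir / "novel_ids.tsv")
    logger.info("novelty screen: %d of %d models are unannotated",
                len(novel), len(models))

    # --- cascade
    cascade = run_cascade(novel, ann, expression, config.filters)
    report.cascade = cascade
    cascade.to_frame().to_csv(outdir / "cascade_report.tsv", sep="\t", index=False)
    for name, ids in zip(cascade.stage_names, cascade.surviving_ids):
        _write_id_list(ids, outdir / f"stage_{name}_ids.tsv")
    prioritized = [m for m in novel if m.id in cascade.final_ids]

    # --- ORF filter
    if config.genome is not None:
        import pyfaidx

        genome = pyfaidx.Fasta(config.genome)
        orf_rows = []
        survivors = []
        for m in prioritized:
            try:
                seq = extract_spliced_sequence(genome, m)
            except NovtxError as exc:
                raise StageError("orf", str(exc)) from exc
            aa = longest_orf_length(seq)
            keep = aa >= config.min_orf_aa
            orf_rows.append({"transcript_id": m.id, "longest_orf_aa": aa, "pass": keep})
            if keep:
                survivors.append(m)
        pd.DataFrame(orf_rows, columns=["transcript_id", "longest_orf_aa", "pass"]).sort_values(
            "transcript_id"
        ).to_csv(outdir / "orf_report.tsv", sep="\t", index=False)
        candidates = survivors
    else:
        candidates = prioritized
    report.orf_pass_count = len(candidates)
    report.candidate_ids = [m.id for m in candidates]

    # --- homology triage (over the whole unannotated set, as a landscape)
    if config.hits is not None and novel:
        hits = nio.read_homology_tsv(config.hits)
        categories = classify_homology(
            hits, [m.id for m in novel], config.evalue_max, config.bitscore_min
        )
        report.homology_summary = summarize_homology(categories)
        pd.DataFrame(
            sorted((q, c.value) for q, c in categories.items()),
            columns=["transcript_id", "category"],
        ).to_csv(outdir / "homology_report.tsv", sep="\t", index=False)

    # --- primer / in-silico PCR validation
    if config.primers is not None and config.genome is not None:
        genome_seq = nio.read_fasta(config.genome)
        primer_df = pd.read_csv(config.primers, sep="\t")
        by_id = {m.id: m for m in models}
        pcr_rows = []
        for row in primer_df.itertuples(index=False):
            model = by_id.get(row.transcript_id)
            pair = PrimerPair(str(row.name), str(row.forward), str(row.reverse))
            ok, reasons = check_primer_constraints(pair, params=config.thermo)
            entry = {
                "name": pair.name,
                "transcript_id": row.transcript_id,
                "constraints_pass": ok,
                "constraint_reasons": "; ".join(reasons),
            }
            if model is not None:
                target = model.span
                amplicons = insilico_pcr(genome_seq, pair, max_product=target.length)
                entry["n_amplicons"] = len(amplicons)
                entry["specific"] = assess_specificity(amplicons, target)
                spans, why = amplicon_spans_all_exons(model, pair, genome=genome_seq)
                entry["spans_all_exons"] = spans
                entry["span_reason"] = why or ""
            pcr_rows.append(entry)
        report.pcr = pcr_rows
        pd.DataFrame(pcr_rows).to_csv(outdir / "pcr_report.tsv", sep="\t", index=False)

    # --- synteny contexts around the final candidates
    if config.orthologs is not None and config.blocks is not None:
        orth = nio.read_orthologs_tsv(config.orthologs)
        blocks = nio.read_blocks_tsv(config.blocks)
        syn_rows = []
        for m in candidates:
            ctx = build_context(m.span, ann, target_span=config.synteny_span)
            attach_orthologs(ctx, orth)
            attach_blocks(ctx, blocks)
            for species in config.synteny_species:
                syn_rows.append(
                    {
                        "transcript_id": m.id,
                        "species": species,
                        "n_genes": ctx.n_genes,
                        "partial": ctx.partial,
                        "synteny_percent": conserved_synteny_fraction(ctx, species),
                        "inversion": detect_inversion(ctx, species),
                        "tau": round(gene_order_tau(ctx, species), 4),
                        "coverage_percent": round(
                            alignment_coverage_percent(ctx, species), 2
                        ),
                    }
                )
        report.synteny = syn_rows
        pd.DataFrame(syn_rows).to_csv(outdir / "synteny_report.tsv", sep="\t", index=False)

    report.provenance = {
        "config_hash": config.config_hash(),
        "novtx_version": __version__,
        "seed": config.seed,
    }
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return report
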