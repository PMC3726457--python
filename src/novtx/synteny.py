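"""Locus-context comparative analysis around a candidate transcript.

For each candidate an approximately 1-Mb window is built around its locus,
sized so that both ends are anchored by an annotated gene.  Against each
comparison species the module computes:

- the conserved-synteny fraction: the percentage of genes in the window
  whose ortholog lies on the modal target chromosome of the window,
- a whole-window inversion call: negative Kendall rank correlation between
  source and target gene order,
- alignment coverage: percent of the window covered by the union of
  cross-species alignment blocks,
- a flank-conservation profile for the genes immediately neighboring the
  candidate (a local "novel island" signal).

Orthologs and alignment blocks are consumed as precomputed tables; this
module performs no sequence alignment or ortholog inference itself, and can
emit dot-plot point sets for external plotting.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy import stats

from .core import AnnotationFeature, AnnotationSet, GenomicInterval


@dataclass(frozen=True)
class OrthologRecord:
    """One source gene's ortholog placement in one comparison species."""

    source_gene: str
    species: str
    target_gene: str | None = None
    target_position: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if (self.target_gene is None) != (self.target_position is None):
            raise ValueError(
                f"{self.source_gene}/{self.species}: target gene and position "
                "must be jointly present or jointly absent"
            )

    @property
    def has_target(self) -> bool:
        return self.target_gene is not None


@dataclass
class SyntenyContext:
    """An anchored comparison window around one candidate locus."""

    focus: GenomicInterval
    interval: GenomicInterval
    genes: list[AnnotationFeature]
    orthologs: dict[str, dict[str, OrthologRecord]] = field(default_factory=dict)
    alignment_blocks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.interval.contains(self.focus):
            raise ValueError("context interval must contain the focus")
        self.genes = sorted(self.genes, key=lambda g: g.interval.start)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def species_records(self, species: str) -> list[OrthologRecord]:
        table = self.orthologs.get(species, {})
        return [table[g.id] for g in self.genes if g.id in table]


def build_context(
    focus: GenomicInterval,
    ann: AnnotationSet,
    target_span: int = 1_000_000,
    chrom_length: int | None = None,
) -> SyntenyContext:
    """Grow a window symmetrically from ``focus`` to ``target_span``, then
    extend each edge outward to wholly include the nearest gene on that
    flank.  If a flank has no gene before the chromosome end, the context is
    flagged partial."""
    center = (focus.start + focus.end) // 2
    half = max(target_span // 2, (focus.length + 1) // 2)
    left = max(1, center - half)
    right = center + half
    if chrom_length is not None:
        right = min(right, chrom_length)

    feats = ann.features_on(focus.chrom)
    partial = False

    # left anchor: nearest gene at or beyond the left edge
    candidates = [f for f in feats if f.interval.start < left]
    straddlers = [f for f in candidates if f.interval.end >= left]
    if straddlers:
        left = min(f.interval.start for f in straddlers)
    elif candidates:
        anchor = max(candidates, key=lambda f: f.interval.end)
        left = anchor.interval.start
    elif not any(f.interval.start >= left and f.interval.end <= right and f.interval.end < focus.start for f in feats):
        partial = True

    # right anchor
    candidates = [f for f in feats if f.interval.end > right]
    straddlers = [f for f in candidates if f.interval.start <= right]
    if straddlers:
        right = max(f.interval.end for f in straddlers)
    elif candidates:
        anchor = min(candidates, key=lambda f: f.interval.start)
        right = anchor.interval.end
    elif not any(f.interval.start >= left and f.interval.end <= right and f.interval.start > focus.end for f in feats):
        partial = True

    interval = GenomicInterval(focus.chrom, left, right)
    genes = [f for f in feats if interval.contains(f.interval)]
    return SyntenyContext(focus=focus, interval=interval, genes=genes, partial=partial)


def attach_orthologs(ctx: SyntenyContext, table: pd.DataFrame) -> None:
    """Load ortholog records relevant to the context's genes from a tidy
    table (columns: source_gene, species, target_gene, target_chrom,
    target_start, target_end, target_strand)."""
    gene_ids = {g.id for g in ctx.genes}
    for row in table.itertuples(index=False):
        if row.source_gene not in gene_ids:
            continue
        if isinstance(row.target_gene, str) and row.target_gene not in ("", "NA"):
            pos = GenomicInterval(
                str(row.target_chrom), int(row.target_start), int(row.target_end),
                row.target_strand if row.target_strand in "+-" else ".",
            )
            rec = OrthologRecord(row.source_gene, row.species, row.target_gene, pos)
        else:
            rec = OrthologRecord(row.source_gene, row.species)
        ctx.orthologs.setdefault(row.species, {})[row.source_gene] = rec


def attach_blocks(ctx: SyntenyContext, table: pd.DataFrame) -> None:
    """Load per-species alignment blocks overlapping the context interval."""
    for row in table.itertuples(index=False):
        if str(row.chrom) != ctx.interval.chrom:
            continue
        start = max(int(row.start), ctx.interval.start)
        end = min(int(row.end), ctx.interval.end)
        if start > end:
            continue
        ctx.alignment_blocks.setdefault(row.species, []).append(
            GenomicInterval(ctx.interval.chrom, start, end)
        )


def modal_target_chromosome(ctx: SyntenyContext, species: str) -> str | None:
    """The most common ortholog chromosome among the context's genes; ties
    break to the lexicographically smallest name for determinism."""
    chroms = [
        rec.target_position.chrom
        for rec in ctx.species_records(species)
        if rec.has_target
    ]
    if not chroms:
        return None
    counts = Counter(chroms)
    top = max(counts.values())
    return sorted(c for c, n in counts.items() if n == top)[0]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def conserved_synteny_fraction(ctx: SyntenyContext, species: str) -> int:
    """Percent of the window's genes with an ortholog on the modal target
    chromosome, to the nearest integer.  Denominator is all genes in the
    window (untestable genes count against conservation)."""
    if not ctx.genes:
        return 0
    modal = modal_target_chromosome(ctx, species)
    if modal is None:
        return 0
    table = ctx.orthologs.get(species, {})
    k = sum(
        1
        for g in ctx.genes
        if g.id in table
        and table[g.id].has_target
        and table[g.id].target_position.chrom == modal
    )
    return _round_half_up(100.0 * k / len(ctx.genes))


def _ordered_pairs(ctx: SyntenyContext, species: str) -> list[tuple[int, int]]:
    """(source start, target start) for genes on the modal target chromosome,
    in source order."""
    modal = modal_target_chromosome(ctx, species)
    if modal is None:
        return []
    table = ctx.orthologs.get(species, {})
    pairs = []
    for g in ctx.genes:
        rec = table.get(g.id)
        if rec is not None and rec.has_target and rec.target_position.chrom == modal:
            pairs.append((g.interval.start, rec.target_position.start))
    return pairs


def gene_order_tau(ctx: SyntenyContext, species: str) -> float:
    """Kendall's tau between source and target gene order on the modal
    chromosome; nan with fewer than 3 ortholog pairs."""
    pairs = _ordered_pairs(ctx, species)
    if len(pairs) < 3:
        return math.nan
    tau, _p = stats.kendalltau([p[0] for p in pairs], [p[1] for p in pairs])
    return float(tau)


def detect_inversion(ctx: SyntenyContext, species: str) -> bool | None:
    """True iff the gene order is globally reversed (tau < 0); ``None`` when
    fewer than 3 ortholog pairs make the call indeterminate."""
    tau = gene_order_tau(ctx, species)
    if math.isnan(tau):
        return None
    return tau < 0


def union_length(blocks: Iterable[GenomicInterval]) -> int:
    """Total bases covered by the union of (possibly overlapping) blocks."""
    spans = sorted((b.start, b.end) for b in blocks)
    total = 0
    cur_start, cur_end = None, None
    for start, end in spans:
        if cur_end is None or start > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def alignment_coverage_percent(ctx: SyntenyContext, species: str) -> float:
    """Percent of the window covered by the union of alignment blocks.
    Overlapping blocks are unioned, never double-counted."""
    blocks = ctx.alignment_blocks.get(species, [])
    if not blocks:
        return 0.0
    return 100.0 * union_length(blocks) / ctx.interval.length


@dataclass(frozen=True)
class FlankGene:
    gene_id: str
    side: str  # "upstream" | "downstream"
    rank: int  # 1 = nearest to the focus
    has_ortholog: bool
    on_modal_chromosome: bool


def flank_conservation_profile(
    ctx: SyntenyContext, species: str, k: int = 2
) -> list[FlankGene]:
    """Ortholog presence for the ``k`` genes immediately up/downstream of the
    focus.  A gene with an ortholog on a non-modal chromosome is reported as
    present but outside the conserved region.  Fewer than ``k`` flank genes
    simply yields a shorter report."""
    modal = modal_target_chromosome(ctx, species)
    table = ctx.orthologs.get(species, {})
    upstream = [g for g in ctx.genes if g.interval.end < ctx.focus.start]
    downstream = [g for g in ctx.genes if g.interval.start > ctx.focus.end]
    out: list[FlankGene] = []
    for rank, g in enumerate(reversed(upstream[-k:]), 1):
        rec = table.get(g.id)
        has = rec is not None and rec.has_target
        on_modal = bool(has and modal is not None and rec.target_position.chrom == modal)
        out.append(FlankGene(g.id, "upstream", rank, has, on_modal))
    for rank, g in enumerate(downstream[:k], 1):
        rec = table.get(g.id)
        has = rec is not None and rec.has_target
        on_modal = bool(has and modal is not None and rec.target_position.chrom == modal)
        out.append(FlankGene(g.id, "downstream", rank, has, on_modal))
    return out


def dotplot_points(ctx: SyntenyContext, species: str) -> pd.DataFrame:
    """(source position, target position) pairs for external dot plotting."""
    pairs = _ordered_pairs(ctx, species)
    return pd.DataFrame(pairs, columns=["source_start", "target_start"])
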