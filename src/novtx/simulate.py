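"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the statistical shape of the study cohort: 428
unannotated transcript models with 2-9 exons (median 2), spliced lengths in
74-10,401 bp, per-model read depths in 19-3,042, a trimodal
distance-to-nearest-gene distribution with peaks near 1,000 / 20,000 /
200,000 bp, an 8-tissue expression matrix with a tissue-restricted subset,
and homology categories near 46 / 13 / 41 %.  Under the paper preset,
exactly 36 transcripts are planted to pass all four prioritization filters.

Planting is by construction, not rejection at the cohort level: each
transcript's depth, distance, exon count, expression row and spliced
sequence are drawn or built so that its truth labels hold exactly, which
makes every downstream stage test deterministic.  Sequence-level features
(ORF content) are spliced into the emitted genome so that extraction +
translation reproduce the planted labels.

Everything is reproducible per seed: the same :class:`GeneratorConfig`
yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    AnnotationFeature,
    AnnotationSet,
    ExpressionRow,
    GenomicInterval,
    TranscriptModel,
)
from .homology import HomologyCategory
from .orfs import reverse_complement
from .prioritize import grubbs_statistic
from .synteny import OrthologRecord, SyntenyContext
from . import io as nio

TISSUES = [
    "cerebellum", "testis", "liver", "kidney", "heart", "lung", "muscle", "skin",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# every 12-mer below carries a TAA fully inside it in all three frame phases,
# and it is its own reverse complement, so stamping it kills long ORFs on
# both strands
_STOP_CASSETTE = b"TTAATTAATTAA"

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-shape settings; defaults are the study conditions."""

    seed: int = 0
    n_transcripts: int = 428
    n_all_pass: int = 36
    n_overlapping_decoys: int = 24
    exon_count_range: tuple[int, int] = (2, 9)
    length_range: tuple[int, int] = (74, 10401)
    length_log_mean: float = math.log(420.0)
    length_log_sigma: float = 0.8
    depth_range: tuple[float, float] = (19.0, 3042.0)
    depth_log_mean: float = math.log(55.0)
    depth_log_sigma: float = 0.75
    n_tissues: int = 8
    distance_centers: tuple[float, float, float] = (1000.0, 20000.0, 200000.0)
    distance_weights: tuple[float, float, float] = (0.65, 0.25, 0.10)
    distance_sigma_log: float = 0.5
    homology_proportions: tuple[float, float, float] = (0.46, 0.13, 0.41)
    homology_exact_counts: tuple[int, int, int] | None = None
    p_restricted_background: float = 0.25
    restricted_target_z: float = 2.40
    expression_log_mean: float = math.log(5.0)
    expression_sigma_log: float = 0.5
    min_depth: float = 30.0
    min_distance: float = 5000.0
    min_exons: int = 3
    alpha: float = 0.05
    min_orf_aa: int = 50
    loci_per_chromosome: int = 40

    def __post_init__(self) -> None:
        if abs(sum(self.homology_proportions) - 1.0) > 1e-9:
            raise ValueError("homology proportions must sum to 1")
        for lo, hi in (self.exon_count_range, self.length_range, self.depth_range):
            if lo > hi:
                raise ValueError("ranges must be ordered")
        if self.n_all_pass > self.n_transcripts:
            raise ValueError("n_all_pass cannot exceed n_transcripts")


def paper_preset(seed: int = 0) -> GeneratorConfig:
    """The study-shaped cohort: 428 models, 36 planted all-pass, exact
    homology counts (197, 55, 176)."""
    return GeneratorConfig(seed=seed, homology_exact_counts=(197, 55, 176))


# ---------------------------------------------------------------------------
# low-level draws


def _truncated_lognormal(rng, log_mean, sigma, lo, hi, size=None):
    """Resample out-of-range draws so bounds hold without boundary atoms."""
    scalar = size is None
    n = 1 if scalar else int(size)
    out = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.lognormal(log_mean, sigma, remaining.size)
        out[remaining] = draw
        remaining = remaining[(draw < lo) | (draw > hi)]
        remaining = np.flatnonzero((out < lo) | (out > hi))
    return float(out[0]) if scalar else out


def _draw_distance(rng, cfg: GeneratorConfig, want_pass: bool | None) -> float:
    """One distance from the trimodal log-normal mixture, optionally
    conditioned on the >= 5,000 bp filter outcome."""
    weights = np.asarray(cfg.distance_weights) / sum(cfg.distance_weights)
    for _ in range(1000):
        comp = rng.choice(3, p=weights)
        d = rng.lognormal(math.log(cfg.distance_centers[comp]), cfg.distance_sigma_log)
        d = max(1.0, round(d))
        if want_pass is None:
            return d
        if want_pass and d >= cfg.min_distance:
            return d
        if not want_pass and d < cfg.min_distance:
            return d
    raise RuntimeError("distance conditioning failed to converge")


def _draw_exon_count(rng, cfg: GeneratorConfig, min_count: int) -> int:
    lo, hi = cfg.exon_count_range
    counts = np.arange(lo, hi + 1)
    # heavy at 2 so the cohort median stays 2
    weights = np.array([0.62, 0.17, 0.09, 0.05, 0.03, 0.02, 0.012, 0.008])[: counts.size]
    mask = counts >= min_count
    w = weights * mask
    return int(rng.choice(counts, p=w / w.sum()))


def _split_length(rng, total: int, parts: int, min_part: int = 25) -> list[int]:
    """Random composition of ``total`` into ``parts`` pieces >= ``min_part``."""
    if parts * min_part > total:
        raise ValueError(f"cannot split {total} into {parts} parts of >= {min_part}")
    slack = total - parts * min_part
    cuts = np.sort(rng.integers(0, slack + 1, size=parts - 1))
    pieces = np.diff(np.concatenate(([0], cuts, [slack])))
    return [min_part + int(p) for p in pieces]


# ---------------------------------------------------------------------------
# spliced-sequence design (ORF planting)


def _random_dna(rng, n: int) -> bytes:
    return _BASES[rng.integers(0, 4, n)].tobytes()


def design_spliced_sequence(rng, length: int, passes_orf: bool, min_orf_aa: int = 50) -> str:
    """Random spliced sequence whose longest six-frame peptide run is
    guaranteed >= ``min_orf_aa`` (pass) or < ``min_orf_aa`` (fail)."""
    seq = bytearray(_random_dna(rng, length))
    if passes_orf:
        max_run = length // 3 - 2
        if max_run < min_orf_aa:
            raise ValueError(
                f"length {length} too short to host a {min_orf_aa}-aa ORF"
            )
        run_len = int(rng.integers(min_orf_aa, min(120, max_run) + 1))
        n_codons = length // 3
        codon_start = int(rng.integers(0, n_codons - run_len + 1))
        pos = codon_start * 3
        run = "".join(
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), run_len)
        )
        seq[pos : pos + run_len * 3] = run.encode()
    elif length >= len(_STOP_CASSETTE):
        step = 100
        for pos in range(0, length - len(_STOP_CASSETTE) + 1, step):
            seq[pos : pos + len(_STOP_CASSETTE)] = _STOP_CASSETTE
        seq[length - len(_STOP_CASSETTE) :] = _STOP_CASSETTE
    return seq.decode()


# ---------------------------------------------------------------------------
# expression


def _background_row(rng, cfg: GeneratorConfig) -> np.ndarray:
    return rng.lognormal(cfg.expression_log_mean, cfg.expression_sigma_log, cfg.n_tissues)


def _make_restricted_row(rng, cfg: GeneratorConfig, tissue: int) -> np.ndarray:
    """Boost one tissue so the Grubbs statistic hits the planted target.

    The statistic is bounded above by (n-1)/sqrt(n) (2.4749 at n = 8), so the
    target must sit below that; the solve is monotone in the boosted value.
    """
    target = cfg.restricted_target_z
    bound = (cfg.n_tissues - 1) / math.sqrt(cfg.n_tissues)
    if target >= bound:
        raise ValueError(f"target Z {target} unreachable; bound is {bound:.4f}")
    others = rng.lognormal(cfg.expression_log_mean, cfg.expression_sigma_log,
                           cfg.n_tissues - 1)

    def z_of(x: float) -> float:
        vals = np.append(others, x)
        s = vals.std(ddof=1)
        return (x - vals.mean()) / s - target

    lo = float(others.max()) * 1.0001 + 1e-9
    hi = lo + 1.0
    while z_of(hi) < 0:
        hi *= 2.0
        if hi > 1e18:
            raise RuntimeError("boost solve failed")
    x = optimize.brentq(z_of, lo, hi, xtol=1e-10)
    row = np.empty(cfg.n_tissues)
    row[np.arange(cfg.n_tissues) != tissue] = others
    row[tissue] = x
    return row


def _make_unrestricted_row(rng, cfg: GeneratorConfig, margin: float = 2.0) -> np.ndarray:
    """Background row conditioned (by construction) to stay unflagged: any
    accidental upper outlier is pulled back to the geometric mean of the
    remaining tissues until the statistic sits below ``margin`` (< the 2.13
    critical value)."""
    row = _background_row(rng, cfg)
    for _ in range(cfg.n_tissues + 4):
        max_z, idx = grubbs_statistic(row)
        if math.isnan(max_z) or max_z <= margin:
            return row
        rest = np.delete(row, idx)
        row[idx] = math.exp(np.log(rest).mean())
    return row


def generate_expression(
    cfg: GeneratorConfig,
    transcript_ids: Sequence[str] | None = None,
    restricted: dict[str, int] | None = None,
    rng=None,
    enforce_labels: bool = True,
) -> tuple[list[ExpressionRow], pd.DataFrame]:
    """Expression rows plus truth.

    ``restricted`` maps transcript id -> boosted tissue index for planted
    tissue-restricted rows; all other rows are background.  With
    ``enforce_labels=False`` background rows are left i.i.d. (unconditioned),
    which is the mode used to measure the outlier test's false-positive rate.
    """
    if cfg.n_tissues < 3:
        raise ValueError("need at least 3 tissues")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if transcript_ids is None:
        transcript_ids = [f"UU{i + 1}" for i in range(cfg.n_transcripts)]
    restricted = restricted or {}
    tissues = TISSUES[: cfg.n_tissues] if cfg.n_tissues <= len(TISSUES) else [
        f"tissue_{i + 1}" for i in range(cfg.n_tissues)
    ]
    rows, truth = [], []
    for tid in transcript_ids:
        if tid in restricted:
            t = restricted[tid]
            row = _make_restricted_row(rng, cfg, t)
            is_restricted, tissue_name = True, tissues[t]
        else:
            row = (
                _make_unrestricted_row(rng, cfg)
                if enforce_labels
                else _background_row(rng, cfg)
            )
            is_restricted, tissue_name = False, ""
        rows.append(ExpressionRow(tid, [float(v) for v in row], list(tissues)))
        truth.append((tid, is_restricted, tissue_name))
    truth_df = pd.DataFrame(
        truth, columns=["transcript_id", "is_tissue_restricted", "restricted_tissue"]
    )
    return rows, truth_df


# ---------------------------------------------------------------------------
# homology


def generate_homology_table(
    cfg: GeneratorConfig,
    transcript_ids: Sequence[str],
    rng=None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Hit rows whose classification recovers the planted categories exactly.

    Categories are assigned by exact counts when
    ``cfg.homology_exact_counts`` is set, else multinomially at the
    configured proportions.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ids = list(transcript_ids)
    n = len(ids)
    if cfg.homology_exact_counts is not None:
        counts = list(cfg.homology_exact_counts)
        if sum(counts) != n:
            raise ValueError(f"exact counts {counts} do not sum to {n}")
    else:
        counts = list(rng.multinomial(n, cfg.homology_proportions))
    labels = (
        [HomologyCategory.ANNOTATED_GENE] * counts[0]
        + [HomologyCategory.UNANNOTATED_OR_BELOW_THRESHOLD] * counts[1]
        + [HomologyCategory.NO_ALIGNMENT] * counts[2]
    )
    order = rng.permutation(n)
    truth = pd.Series(
        {ids[i]: labels[k].value for k, i in enumerate(order)}, name="homology_category"
    )

    records = []

    def _hit_row(qid, evalue, bitscore, annotated, description):
        qstart = int(rng.integers(1, 50))
        aln = int(rng.integers(80, 600))
        sstart = int(rng.integers(1, 5_000_000))
        records.append(
            {
                "qseqid": qid,
                "sseqid": f"XM_{rng.integers(10**6, 10**7)}",
                "pident": round(float(rng.uniform(78, 99.5)), 2),
                "length": aln,
                "mismatch": int(rng.integers(0, 30)),
                "gapopen": int(rng.integers(0, 5)),
                "qstart": qstart,
                "qend": qstart + aln - 1,
                "sstart": sstart,
                "send": sstart + aln - 1,
                "evalue": float(evalue),
                "bitscore": round(float(bitscore), 1),
                "subject_description": description,
                "is_annotated": int(annotated),
            }
        )

    species_pool = ["Bos taurus", "Canis lupus familiaris", "Homo sapiens", "Sus scrofa"]
    for tid in ids:
        cat = truth[tid]
        if cat == HomologyCategory.ANNOTATED_GENE.value:
            sp = species_pool[rng.integers(0, len(species_pool))]
            _hit_row(
                tid,
                10.0 ** rng.uniform(-40, -6),
                rng.uniform(110, 600),
                True,
                f"{sp} mRNA, transcript variant",
            )
            for _ in range(int(rng.integers(0, 2))):
                _hit_row(tid, 10.0 ** rng.uniform(-4, -1), rng.uniform(40, 95),
                         False, "genomic scaffold, unplaced")
        elif cat == HomologyCategory.UNANNOTATED_OR_BELOW_THRESHOLD.value:
            mode = rng.integers(0, 3)
            if mode == 0:  # fails e-value
                _hit_row(tid, 10.0 ** rng.uniform(-4.9, -1), rng.uniform(110, 300),
                         True, "predicted mRNA")
            elif mode == 1:  # fails bit score
                _hit_row(tid, 10.0 ** rng.uniform(-20, -6), rng.uniform(40, 99),
                         True, "mRNA fragment")
            else:  # subject not annotated as a gene
                _hit_row(tid, 10.0 ** rng.uniform(-30, -6), rng.uniform(110, 400),
                         False, "uncharacterized genomic contig")
    df = pd.DataFrame(records, columns=nio.HIT_COLUMNS)
    return df, truth


# ---------------------------------------------------------------------------
# cohort planner: coordinates, labels, sequence


@dataclass
class SyntheticCohort:
    """Everything one seed produces, with the planted truth table."""

    config: GeneratorConfig
    genome: dict[str, str] | None
    annotation: AnnotationSet
    models: list[TranscriptModel]
    truth: pd.DataFrame
    expression: list[ExpressionRow]
    hits: pd.DataFrame
    orthologs: pd.DataFrame
    blocks: pd.DataFrame

    @property
    def all_pass_ids(self) -> set[str]:
        t = self.truth
        mask = (
            t.is_novel
            & t.passes_depth & t.passes_distance & t.passes_exons
            & t.is_tissue_restricted
        )
        return set(t.loc[mask, "transcript_id"])


def _plan_transcript(rng, cfg: GeneratorConfig, forced_pass: bool):
    """Draw (depth, distance, n_exons, spliced_length) honoring the planted
    outcome; labels for the three scalar filters follow from the values."""
    if forced_pass:
        depth = _truncated_lognormal(rng, cfg.depth_log_mean, cfg.depth_log_sigma,
                                     cfg.min_depth, cfg.depth_range[1])
        distance = _draw_distance(rng, cfg, want_pass=True)
        n_exons = _draw_exon_count(rng, cfg, cfg.min_exons)
        min_len = max(cfg.min_orf_aa * 3 + 30, n_exons * 30)
        length = _truncated_lognormal(rng, cfg.length_log_mean, cfg.length_log_sigma,
                                      min_len, cfg.length_range[1])
    else:
        depth = _truncated_lognormal(rng, cfg.depth_log_mean, cfg.depth_log_sigma,
                                     *cfg.depth_range)
        distance = _draw_distance(rng, cfg, want_pass=None)
        n_exons = _draw_exon_count(rng, cfg, cfg.exon_count_range[0])
        length = _truncated_lognormal(rng, cfg.length_log_mean, cfg.length_log_sigma,
                                      *cfg.length_range)
        n_exons = min(n_exons, int(length) // 30) or cfg.exon_count_range[0]
        n_exons = max(n_exons, cfg.exon_count_range[0])
        if n_exons * 30 > length:
            length = float(n_exons * 30)
    # depth is emitted at 0.1-read precision; round here so the planted
    # pass/fail label and the emitted value can never disagree
    return round(depth, 1), float(distance), int(n_exons), int(length)


def simulate_cohort(cfg: GeneratorConfig, with_sequence: bool = True) -> SyntheticCohort:
    """Build one fully planted cohort (deterministic per ``cfg.seed``)."""
    root = np.random.SeedSequence(cfg.seed)
    (rng_plan, rng_seq, rng_expr, rng_hom, rng_orth) = [
        np.random.default_rng(s) for s in root.spawn(5)
    ]

    n = cfg.n_transcripts
    ids = [f"UU{i + 1}" for i in range(n)]
    forced = set(rng_plan.choice(n, size=cfg.n_all_pass, replace=False).tolist())

    plans = []
    for i in range(n):
        depth, distance, n_exons, length = _plan_transcript(rng_plan, cfg, i in forced)
        passes_orf = (
            True if i in forced
            else (length >= cfg.min_orf_aa * 3 + 30 and rng_plan.random() < 0.5)
        )
        if i in forced:
            restricted = True
        else:
            scalar_pass = (
                depth >= cfg.min_depth
                and distance >= cfg.min_distance
                and n_exons >= cfg.min_exons
            )
            # an accidental all-pass would blur the planted candidate set
            restricted = (not scalar_pass) and rng_plan.random() < cfg.p_restricted_background
        plans.append(
            dict(id=ids[i], depth=depth, distance=distance, n_exons=n_exons,
                 length=length, passes_orf=passes_orf, restricted=restricted,
                 forced=i in forced)
        )

    # ---- layout: chromosomes tiled as [gene] gap [transcript] gap [gene] ...
    ann = AnnotationSet()
    models: list[TranscriptModel] = []
    chrom_lengths: dict[str, int] = {}
    placements: list[tuple[TranscriptModel, str]] = []  # (model, designed spliced seq)
    gene_counter = 0
    chrom_idx = 0
    per_chrom = cfg.loci_per_chromosome

    for batch_start in range(0, n, per_chrom):
        chrom_idx += 1
        chrom = f"chr{chrom_idx}"
        cursor = 10_000
        batch = plans[batch_start : batch_start + per_chrom]
        for plan in batch:
            gene_counter += 1
            glen = int(rng_plan.integers(500, 3000))
            biotype = "pseudogene" if rng_plan.random() < 0.08 else "protein_coding"
            ann.add(
                AnnotationFeature(
                    f"G{gene_counter}",
                    GenomicInterval(chrom, cursor, cursor + glen - 1,
                                    "+" if rng_plan.random() < 0.5 else "-"),
                    biotype,
                )
            )
            cursor += glen + int(plan["distance"])

            strand = "+" if rng_plan.random() < 0.5 else "-"
            exon_lengths = _split_length(rng_plan, plan["length"], plan["n_exons"])
            exons = []
            pos = cursor
            for k, elen in enumerate(exon_lengths):
                exons.append(GenomicInterval(chrom, pos, pos + elen - 1, strand))
                if k < len(exon_lengths) - 1:
                    pos += elen + int(rng_plan.integers(80, 2500))
                else:
                    pos += elen
            model = TranscriptModel(plan["id"], exons, depth=float(round(plan["depth"], 1)))
            model.junction_support = [
                (iv, max(1, int(model.depth * rng_plan.uniform(0.3, 0.9))))
                for iv in model.introns
            ]
            models.append(model)
            spliced = design_spliced_sequence(
                rng_seq, plan["length"], plan["passes_orf"], cfg.min_orf_aa
            )
            placements.append((model, spliced))
            # the next gene must sit farther than the planted distance
            cursor = model.span.end + 1 + int(plan["distance"]) + 1 + int(
                rng_plan.integers(0, 500)
            )
        # closing anchor gene so the last transcript's right flank is bounded
        gene_counter += 1
        glen = int(rng_plan.integers(500, 3000))
        ann.add(
            AnnotationFeature(
                f"G{gene_counter}",
                GenomicInterval(chrom, cursor, cursor + glen - 1, "+"),
            )
        )
        chrom_lengths[chrom] = cursor + glen + 10_000

    # ---- decoy models overlapping annotation (removed by the novelty screen)
    decoys = []
    genes = list(ann)
    for d in range(cfg.n_overlapping_decoys):
        g = genes[rng_plan.integers(0, len(genes))]
        giv = g.interval
        start = giv.start + int(rng_plan.integers(0, max(1, giv.length // 2)))
        end = min(giv.end + int(rng_plan.integers(0, 500)), chrom_lengths[giv.chrom] - 1)
        end = max(end, start + 100)
        mid = (start + end) // 2
        decoy = TranscriptModel(
            f"OV{d + 1}",
            [
                GenomicInterval(giv.chrom, start, mid - 50, "+"),
                GenomicInterval(giv.chrom, mid + 50, end, "+"),
            ],
            depth=float(round(_truncated_lognormal(
                rng_plan, cfg.depth_log_mean, cfg.depth_log_sigma, *cfg.depth_range
            ), 1)),
        )
        decoys.append(decoy)

    # ---- genome sequence with planted exon content spliced in
    genome: dict[str, str] | None = None
    if with_sequence:
        genome_bytes = {
            chrom: bytearray(_random_dna(rng_seq, length))
            for chrom, length in chrom_lengths.items()
        }
        for model, spliced in placements:
            genomic = spliced if model.strand == "+" else reverse_complement(spliced)
            buf = genome_bytes[model.chrom]
            pos = 0
            for exon in model.exons:
                buf[exon.start - 1 : exon.end] = genomic[pos : pos + exon.length].encode()
                pos += exon.length
        genome = {chrom: buf.decode() for chrom, buf in genome_bytes.items()}

    # ---- expression, homology, ortholog/block tables
    tissue_of = {
        p["id"]: int(rng_expr.integers(0, cfg.n_tissues))
        for p in plans
        if p["restricted"]
    }
    all_ids = ids + [d.id for d in decoys]
    expression, expr_truth = generate_expression(
        cfg, all_ids, restricted=tissue_of, rng=rng_expr
    )
    hits, hom_truth = generate_homology_table(cfg, ids, rng=rng_hom)
    orthologs, blocks = _cohort_comparative_tables(rng_orth, ann, chrom_lengths)

    # ---- truth table
    rows = []
    for p in plans:
        rows.append(
            dict(
                transcript_id=p["id"],
                is_novel=True,
                depth=round(p["depth"], 1),
                distance_bp=int(p["distance"]),
                n_exons=p["n_exons"],
                spliced_length=p["length"],
                passes_depth=round(p["depth"], 1) >= cfg.min_depth,
                passes_distance=p["distance"] >= cfg.min_distance,
                passes_exons=p["n_exons"] >= cfg.min_exons,
                is_tissue_restricted=p["restricted"],
                restricted_tissue=(
                    TISSUES[tissue_of[p["id"]]] if p["id"] in tissue_of else ""
                ),
                passes_orf=p["passes_orf"],
                homology_category=hom_truth[p["id"]],
            )
        )
    for d in decoys:
        rows.append(
            dict(
                transcript_id=d.id, is_novel=False, depth=d.depth, distance_bp=0,
                n_exons=d.n_exons, spliced_length=d.spliced_length,
                passes_depth=d.depth >= cfg.min_depth, passes_distance=False,
                passes_exons=d.n_exons >= cfg.min_exons,
                is_tissue_restricted=False, restricted_tissue="",
                passes_orf=False, homology_category="",
            )
        )
    truth = pd.DataFrame(rows)

    return SyntheticCohort(
        config=cfg,
        genome=genome,
        annotation=ann,
        models=models + decoys,
        truth=truth,
        expression=expression,
        hits=hits,
        orthologs=orthologs,
        blocks=blocks,
    )


def _cohort_comparative_tables(rng, ann: AnnotationSet, chrom_lengths: dict[str, int]):
    """Ortholog and alignment-block tables across the whole cohort genome,
    order-preserving per chromosome with ~73% block coverage."""
    species_list = ["human", "dog", "cattle"]
    orth_rows = []
    for species in species_list:
        for chrom in sorted(chrom_lengths):
            feats = ann.features_on(chrom)
            target_chrom = f"{species[0]}chr{chrom[3:]}"
            tpos = 50_000
            for feat in feats:
                u = rng.random()
                if u < 0.65:
                    tlen = int(rng.integers(500, 3000))
                    orth_rows.append(
                        (feat.id, species, f"{species[:2].upper()}_{feat.id}",
                         target_chrom, tpos, tpos + tlen - 1, feat.interval.strand)
                    )
                    tpos += tlen + int(rng.integers(1000, 50_000))
                elif u < 0.75:  # ortholog outside the conserved chromosome
                    tlen = int(rng.integers(500, 3000))
                    off = f"{species[0]}chr{int(rng.integers(30, 40))}"
                    start = int(rng.integers(1, 10_000_000))
                    orth_rows.append(
                        (feat.id, species, f"{species[:2].upper()}_{feat.id}",
                         off, start, start + tlen - 1, feat.interval.strand)
                    )
                else:
                    orth_rows.append((feat.id, species, "", "", "", "", ""))
    orthologs = pd.DataFrame(orth_rows, columns=nio.ORTHOLOG_COLUMNS)

    block_rows = []
    for species in species_list:
        for chrom in sorted(chrom_lengths):
            length = chrom_lengths[chrom]
            pos = 1
            while pos < length:
                blen = int(rng.integers(2_000, 20_000))
                end = min(pos + blen - 1, length)
                block_rows.append((species, chrom, pos, end))
                gap = int(rng.integers(800, 7_500))  # ~73% expected coverage
                pos = end + 1 + gap
    blocks = pd.DataFrame(block_rows, columns=nio.BLOCK_COLUMNS)
    return orthologs, blocks


# ---------------------------------------------------------------------------
# spec-level convenience operations


def generate_genome(cfg: GeneratorConfig) -> dict[str, str]:
    """The cohort genome (chrom -> sequence), reproducible per seed."""
    return simulate_cohort(cfg, with_sequence=True).genome


def generate_annotation_and_models(
    cfg: GeneratorConfig, genome: dict[str, str] | None = None
) -> tuple[AnnotationSet, list[TranscriptModel], pd.DataFrame]:
    """Annotation, transcript models and truth table for ``cfg``.

    Placement is seed-deterministic, so the result is consistent with the
    genome returned by :func:`generate_genome` for the same config.
    """
    cohort = simulate_cohort(cfg, with_sequence=False)
    return cohort.annotation, cohort.models, cohort.truth


# ---------------------------------------------------------------------------
# standalone synteny-context generator (exact planted truth)


def generate_synteny_context(
    cfg: GeneratorConfig,
    rng=None,
    n_genes: int | None = None,
    synteny_percent: int = 75,
    inversion: bool = False,
    flank_null: int = 0,
    coverage_percent: float = 73.0,
    species: str = "human",
) -> tuple[SyntenyContext, dict]:
    """One anchored ~1-Mb context with planted gene count, conserved-synteny
    fraction, optional whole-interval inversion, optional non-orthologous
    flank genes, and exact alignment-block coverage."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if n_genes is None:
        n_genes = int(rng.integers(19, 26))  # study contexts held 19-25 genes
    chrom = "ctx_chr"
    span = 1_000_000
    spacing = span // n_genes

    genes = []
    pos = 10_000
    for i in range(n_genes):
        glen = int(rng.integers(2_000, 8_000))
        genes.append(
            AnnotationFeature(f"CTX{i + 1}", GenomicInterval(chrom, pos, pos + glen - 1, "+"))
        )
        pos += glen + spacing - glen
    interval = GenomicInterval(chrom, genes[0].interval.start, genes[-1].interval.end)

    mid = n_genes // 2
    left, right = genes[mid - 1], genes[mid]
    gap_mid = (left.interval.end + right.interval.start) // 2
    focus = GenomicInterval(chrom, gap_mid - 2_000, gap_mid + 2_000)

    ctx = SyntenyContext(focus=focus, interval=interval, genes=genes)

    # flank-null genes: the ones nearest the focus on each side
    null_ids = set()
    ups = [g for g in genes if g.interval.end < focus.start]
    downs = [g for g in genes if g.interval.start > focus.end]
    for g in ups[-flank_null:] if flank_null else []:
        null_ids.add(g.id)
    for g in downs[:flank_null] if flank_null else []:
        null_ids.add(g.id)

    eligible = [g for g in genes if g.id not in null_ids]
    k = int(math.floor(synteny_percent * n_genes / 100.0 + 0.5))
    k = min(k, len(eligible))
    conserved = [g.id for g in eligible[:k]] if k else []
    # keep source order, then invert target order if planted
    modal_chrom = "t_chr1"
    base = 5_000_000
    step = 40_000
    table: dict[str, OrthologRecord] = {}
    order = list(range(len(conserved)))
    target_order = order[::-1] if inversion else order
    for rank, gid in zip(target_order, conserved):
        start = base + rank * step
        table[gid] = OrthologRecord(
            gid, species, f"T_{gid}", GenomicInterval(modal_chrom, start, start + 2_000, "+")
        )
    n_off = min(2, max(0, k - 1))
    off_candidates = [g.id for g in eligible[k:]]
    for j, gid in enumerate(off_candidates[:n_off]):
        start = 1_000_000 + j * 100_000
        table[gid] = OrthologRecord(
            gid, species, f"T_{gid}", GenomicInterval("t_chr9", start, start + 2_000, "+")
        )
    for g in genes:
        table.setdefault(g.id, OrthologRecord(g.id, species))
    ctx.orthologs[species] = table

    # exact-coverage alignment blocks
    L = interval.length
    cov = int(math.floor(coverage_percent / 100.0 * L + 0.5))
    m = int(rng.integers(5, 16))
    m = min(m, cov) or 1
    block_lens = _split_length(rng, cov, m, min_part=1)
    gap_total = L - cov
    gap_lens = _split_length(rng, gap_total + (m + 1), m + 1, min_part=1)
    gap_lens = [g - 1 for g in gap_lens]
    blocks = []
    pos = interval.start + gap_lens[0]
    for blen, gap in zip(block_lens, gap_lens[1:]):
        blocks.append(GenomicInterval(chrom, pos, pos + blen - 1))
        pos += blen + gap
    ctx.alignment_blocks[species] = blocks

    truth = {
        "n_genes": n_genes,
        "synteny_fraction": int(math.floor(100.0 * k / n_genes + 0.5)),
        "inversion": inversion if k >= 3 else None,
        "coverage_percent": 100.0 * cov / L,
        "flank_null_ids": sorted(null_ids),
    }
    return ctx, truth


# ---------------------------------------------------------------------------
# file emission


def simulate_to_dir(cfg: GeneratorConfig, outdir, with_sequence: bool = True) -> Path:
    """Write one cohort to ``outdir`` (genome.fa, genes.gtf, models.gtf,
    depth.tsv, expr.tsv, hits.tsv, orthologs.tsv, blocks.tsv, truth.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg, with_sequence=with_sequence)
    if cohort.genome is not None:
        nio.write_fasta(cohort.genome, outdir / "genome.fa")
    nio.write_annotation(cohort.annotation, outdir / "genes.gtf")
    nio.write_models_gtf(cohort.models, outdir / "models.gtf")
    nio.write_evidence_tsv(cohort.models, outdir / "depth.tsv")
    nio.write_expression_tsv(cohort.expression, outdir / "expr.tsv")
    nio.write_homology_tsv(cohort.hits, outdir / "hits.tsv")
    nio.write_orthologs_tsv(cohort.orthologs, outdir / "orthologs.tsv")
    nio.write_blocks_tsv(cohort.blocks, outdir / "blocks.tsv")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir
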