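"""The four-filter prioritization cascade.

Unannotated transcript models are reduced to a prioritized candidate set by
four per-transcript predicates, applied iteratively:

1. read-coverage depth >= 30 reads,
2. distance to the nearest annotated gene >= 5,000 bp,
3. three or more exons,
4. a tissue-restricted expression pattern, detected as a single high outlier
   among the per-tissue normalized values by the extreme studentized deviate
   (Grubbs) test at alpha = 0.05 (critical value 2.13 for 8 tissues).

Every threshold is inclusive (">= 30", "5,000 or more", "three or more").
The tissue-restriction test flags only *over*-expression: the statistic is
the maximum signed Z-score, so a transcript deviant by absence in one tissue
is not flagged.  The critical value is the classical two-sided Grubbs bound,
which reproduces 2.13 at n = 8 (the one-sided bound would give about 2.03).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import AnnotationSet, ExpressionRow, TranscriptModel, genomic_span

logger = logging.getLogger(__name__)

CASCADE_STAGES = ("depth", "distance", "exons", "tissue_restriction")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults are the study settings."""

    min_depth: float = 30.0
    min_distance: float = 5000.0
    min_exons: int = 3
    alpha: float = 0.05
    n_tissues: int = 8

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_distance <= 0 or self.min_exons <= 0:
            raise ValueError("all thresholds must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def depth_filter(
    models: Iterable[TranscriptModel], min_depth: float = 30.0
) -> list[TranscriptModel]:
    """Keep models whose read-coverage depth is at least ``min_depth``."""
    if min_depth <= 0:
        raise ValueError("min_depth must be > 0")
    return [m for m in models if m.depth >= min_depth]


def nearest_feature_distance(model: TranscriptModel, ann: AnnotationSet) -> float:
    """Distance (bp) from the model's genomic span to the closest annotated
    feature on its chromosome; infinite when the chromosome is unannotated."""
    return ann.nearest_distance(genomic_span(model))


def distance_filter(
    models: Iterable[TranscriptModel], ann: AnnotationSet, min_distance: float = 5000.0
) -> list[TranscriptModel]:
    return [m for m in models if nearest_feature_distance(m, ann) >= min_distance]


def exon_filter(
    models: Iterable[TranscriptModel], min_exons: int = 3
) -> list[TranscriptModel]:
    if min_exons < 1:
        raise ValueError("min_exons must be >= 1")
    return [m for m in models if m.n_exons >= min_exons]


# ---------------------------------------------------------------------------
# extreme studentized deviate (Grubbs) outlier test


def grubbs_statistic(values: Sequence[float]) -> tuple[float, int]:
    """Maximum signed Z-score and the index attaining it.

    Z_i = (x_i - mean) / s with the n-1 (sample) standard deviation.  A
    zero-variance vector is not testable: returns ``(nan, -1)``, which every
    caller treats as "not tissue-restricted".
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Grubbs test needs >= 3 values, got {x.size}")
    s = x.std(ddof=1)
    if s == 0:
        return (math.nan, -1)
    z = (x - x.mean()) / s
    idx = int(np.argmax(z))
    return (float(z[idx]), idx)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs/ESD critical value.

    G = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    G(8, 0.05) = 2.13 to two decimals.
    """
    if n < 3:
        raise ValueError(f"Grubbs critical value needs n >= 3, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return float((n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t)))


@dataclass(frozen=True)
class TissueRestrictionResult:
    transcript_id: str
    max_z: float
    tissue_index: int
    tissue_name: str | None
    flagged: bool
    reason: str | None = None


def tissue_restriction_test(
    rows: Iterable[ExpressionRow], alpha: float = 0.05
) -> list[TissueRestrictionResult]:
    """Apply the Grubbs test to every expression row.

    A row is flagged when its maximum signed Z-score strictly exceeds the
    two-sided critical value for its tissue count.  Zero-variance rows are
    excluded with a logged reason.
    """
    results = []
    crit_cache: dict[int, float] = {}
    for row in rows:
        n = row.n_tissues
        crit = crit_cache.setdefault(n, grubbs_critical(n, alpha))
        max_z, idx = grubbs_statistic(row.values)
        if math.isnan(max_z):
            logger.info("transcript %s: zero variance, not testable", row.transcript_id)
            results.append(
                TissueRestrictionResult(row.transcript_id, math.nan, -1, None, False,
                                        reason="zero_variance")
            )
            continue
        flagged = max_z > crit
        results.append(
            TissueRestrictionResult(
                row.transcript_id, max_z, idx, row.tissue_names[idx], flagged
            )
        )
    return results


def tissue_restriction_filter(
    rows: Iterable[ExpressionRow], alpha: float = 0.05
) -> tuple[list[str], dict[str, str]]:
    """Surviving transcript ids plus the flagged tissue for each survivor."""
    surviving: list[str] = []
    flagged_tissue: dict[str, str] = {}
    for res in tissue_restriction_test(rows, alpha):
        if res.flagged:
            surviving.append(res.transcript_id)
            flagged_tissue[res.transcript_id] = res.tissue_name or ""
    return surviving, flagged_tissue


# ---------------------------------------------------------------------------
# the cascade


@dataclass
class CascadeReport:
    """Per-stage survivor bookkeeping for one cascade run."""

    stage_names: list[str]
    counts_after_stage: list[int]
    surviving_ids: list[set[str]]
    initial_count: int = 0
    flagged_tissue: dict[str, str] = field(default_factory=dict)
    excluded_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def final_ids(self) -> set[str]:
        return self.surviving_ids[-1] if self.surviving_ids else set()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": ["input"] + self.stage_names,
                "count_after": [self.initial_count] + self.counts_after_stage,
            }
        )


def run_cascade(
    models: Sequence[TranscriptModel],
    ann: AnnotationSet,
    expression: Iterable[ExpressionRow],
    config: FilterConfig = FilterConfig(),
) -> CascadeReport:
    """Apply depth -> distance -> exon -> tissue-restriction in order.

    The four predicates are independent per-transcript tests, so the final
    set does not depend on the order; the ordering fixes only the per-stage
    counts reported.  Models with no expression row are excluded at stage 4
    with a logged reason.
    """
    logger.info(
        "cascade thresholds: depth >= %g, distance >= %g bp, exons >= %d, alpha = %g",
        config.min_depth, config.min_distance, config.min_exons, config.alpha,
    )
    expr_by_id: Mapping[str, ExpressionRow] = {r.transcript_id: r for r in expression}

    report = CascadeReport([], [], [], initial_count=len(models))

    stage1 = depth_filter(models, config.min_depth)
    report.stage_names.append("depth")
    report.counts_after_stage.append(len(stage1))
    report.surviving_ids.append({m.id for m in stage1})

    stage2 = distance_filter(stage1, ann, config.min_distance)
    report.stage_names.append("distance")
    report.counts_after_stage.append(len(stage2))
    report.surviving_ids.append({m.id for m in stage2})

    stage3 = exon_filter(stage2, config.min_exons)
    report.stage_names.append("exons")
    report.counts_after_stage.append(len(stage3))
    report.surviving_ids.append({m.id for m in stage3})

    rows = []
    for m in stage3:
        row = expr_by_id.get(m.id)
        if row is None:
            logger.warning("transcript %s has no expression row; excluded", m.id)
            report.excluded_reasons[m.id] = "missing_expression"
        else:
            rows.append(row)
    results = tissue_restriction_test(rows, config.alpha)
    surviving_ids = [r.transcript_id for r in results if r.flagged]
    flagged = {r.transcript_id: r.tissue_name or "" for r in results if r.flagged}
    for res in results:
        if res.reason:
            report.excluded_reasons[res.transcript_id] = res.reason
    report.stage_names.append("tissue_restriction")
    report.counts_after_stage.append(len(surviving_ids))
    report.surviving_ids.append(set(surviving_ids))
    report.flagged_tissue = flagged
    return report
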