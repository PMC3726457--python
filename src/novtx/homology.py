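"""Triage of tabular homology-search hits into three categories.

Each query transcript lands in exactly one category:

- ``annotated_gene``: at least one hit passes the joint significance rule
  (e-value <= 1e-5 AND bit score >= 100) and its subject is annotated as a
  transcribed gene;
- ``no_alignment``: the query produced no hits at all;
- ``unannotated_or_below_threshold``: everything else (hits exist but none
  satisfies all three conditions).

Whether a subject "is annotated as a transcribed gene" is an input column of
the hit table; a regex helper over free-text subject descriptions is
provided for convenience but is not authoritative.
"""

from __future__ import annotations

import enum
import re
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

from .core import HomologyHit


class HomologyCategory(str, enum.Enum):
    ANNOTATED_GENE = "annotated_gene"
    UNANNOTATED_OR_BELOW_THRESHOLD = "unannotated_or_below_threshold"
    NO_ALIGNMENT = "no_alignment"


CATEGORY_ORDER = (
    HomologyCategory.ANNOTATED_GENE,
    HomologyCategory.UNANNOTATED_OR_BELOW_THRESHOLD,
    HomologyCategory.NO_ALIGNMENT,
)

_GENE_DESCRIPTION_RE = re.compile(
    r"\b(mRNA|gene|transcript variant|cDNA|protein|CDS)\b", re.IGNORECASE
)

_UNANNOTATED_RE = re.compile(
    r"\b(uncharacterized|hypothetical|predicted|clone|chromosome .* sequence|"
    r"genomic (?:scaffold|contig)|BAC|unplaced)\b",
    re.IGNORECASE,
)


def description_looks_annotated(description: str) -> bool:
    """Heuristic call on a free-text subject description.  Convenience only:
    the authoritative signal is the hit table's ``is_annotated`` column."""
    if _UNANNOTATED_RE.search(description):
        return False
    return bool(_GENE_DESCRIPTION_RE.search(description))


def classify_homology(
    hits: Iterable[HomologyHit],
    query_ids: Iterable[str],
    evalue_max: float = 1e-5,
    bitscore_min: float = 100.0,
) -> dict[str, HomologyCategory]:
    """Assign one category per query.

    ``query_ids`` is the full query universe; queries absent from the hit
    table are ``no_alignment``.  The three significance conditions are
    connected by AND.
    """
    if evalue_max <= 0 or bitscore_min <= 0:
        raise ValueError("thresholds must be positive")
    by_query: dict[str, list[HomologyHit]] = defaultdict(list)
    for hit in hits:
        by_query[hit.query_id].append(hit)

    out: dict[str, HomologyCategory] = {}
    for qid in query_ids:
        qhits = by_query.get(qid, [])
        if not qhits:
            out[qid] = HomologyCategory.NO_ALIGNMENT
        elif any(
            h.evalue <= evalue_max
            and h.bitscore >= bitscore_min
            and h.subject_is_annotated_gene
            for h in qhits
        ):
            out[qid] = HomologyCategory.ANNOTATED_GENE
        else:
            out[qid] = HomologyCategory.UNANNOTATED_OR_BELOW_THRESHOLD
    return out


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def summarize_homology(
    categories: Mapping[str, HomologyCategory] | Sequence[HomologyCategory],
) -> dict[str, dict[str, int]]:
    """Counts and nearest-integer percentages per category.

    The study's counts (197, 55, 176) of 428 summarize as 46% / 13% / 41%.
    """
    values = (
        list(categories.values()) if isinstance(categories, Mapping) else list(categories)
    )
    if not values:
        raise ValueError("no queries to summarize")
    counts = Counter(values)
    total = len(values)
    return {
        cat.value: {
            "count": counts.get(cat, 0),
            "percent": _round_half_up(100.0 * counts.get(cat, 0) / total),
        }
        for cat in CATEGORY_ORDER
    }
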