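"""Independent brute-force oracles used by the equivalence tests.

Each oracle recomputes a quantity by the most literal method available
(per-base scans, quadratic enumeration, an external translation routine) so
that agreement with the package's optimized path is meaningful.
"""

import numpy as np
from Bio.Seq import Seq


def brute_gap_bases(a_start, a_end, b_start, b_end):
    """Count bases strictly between two closed intervals by scanning."""
    lo = min(a_end, b_end) + 1
    hi = max(a_start, b_start) - 1
    count = 0
    for x in range(lo, hi + 1):
        if (a_start <= x <= a_end) or (b_start <= x <= b_end):
            continue
        count += 1
    return count


def brute_nearest_distance(span, features):
    """Exhaustive scan over every feature interval."""
    best = None
    for f in features:
        if f.chrom != span.chrom:
            continue
        if span.start <= f.end and f.start <= span.end:
            d = 0
        else:
            d = brute_gap_bases(span.start, span.end, f.start, f.end)
        best = d if best is None else min(best, d)
    return float("inf") if best is None else float(best)


def brute_longest_orf(dna):
    """Longest stop-free peptide run over six frames, translated by
    biopython's own translator (an implementation independent of the
    package's codon-table path).  ACGT-only input."""
    rc = str(Seq(dna).reverse_complement())
    best = 0
    for template in (dna, rc):
        for off in range(3):
            sub = template[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate()) if sub else ""
            for seg in pep.split("*"):
                best = max(best, len(seg))
    return best


def brute_pcr_products(genome, forward, reverse, max_product):
    """Quadratic enumeration of all (plus-site, minus-site) placements in
    both pair orientations; returns {(chrom, start, end)} in 1-based
    inclusive coordinates."""
    rc = lambda s: str(Seq(s).reverse_complement())
    products = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for p_plus, p_minus in ((forward, reverse), (reverse, forward)):
            lp, lm = len(p_plus), len(p_minus)
            minus_match = rc(p_minus)
            for i in range(n - lp + 1):
                if seq[i : i + lp] != p_plus:
                    continue
                for j in range(i, n - lm + 1):
                    if seq[j : j + lm] != minus_match:
                        continue
                    size = j + lm - i
                    if size <= max_product and size >= max(lp, lm):
                        products.add((chrom, i + 1, j + lm))
    return products


def bitmap_coverage_percent(blocks, interval):
    """Per-base boolean bitmap union coverage of a window."""
    mask = np.zeros(interval.length, dtype=bool)
    for b in blocks:
        lo = max(b.start, interval.start) - interval.start
        hi = min(b.end, interval.end) - interval.start
        if hi >= lo:
            mask[lo : hi + 1] = True
    return 100.0 * mask.sum() / interval.length


def brute_kendall_tau_sign(xs, ys):
    """Sign of the concordant-minus-discordant pair count (no tie handling;
    inputs are distinct)."""
    s = 0
    n = len(xs)
    for i in range(n):
        for j in range(i + 1, n):
            a = (xs[i] - xs[j]) * (ys[i] - ys[j])
            s += (a > 0) - (a < 0)
    return (s > 0) - (s < 0)
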