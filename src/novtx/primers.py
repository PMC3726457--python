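"""Primer QC and in-silico PCR for expression-validation assays.

Melting temperatures use the nearest-neighbor model with the legacy design
defaults: Breslauer (1986) stack enthalpies/entropies, a -10.8 e.u. helix
initiation entropy, Tm = dH / (dS + R ln(C/4)) - 273.15, and the
Schildkraut-Lifson salt correction 16.6 * log10([Na+]) at 50 mM monovalent
salt and 50 nM annealing oligo.  These settings reproduce the printed assay
Tm values (e.g. TGAGAAGGAAGCCAAGGAAA -> 59.93 degC) to two decimals.  A
SantaLucia (1998) mode is available behind :class:`ThermoParams` since
modern designs use it, delegated to biopython.

In-silico PCR enumerates every genomic site where the forward primer matches
the plus strand and the reverse primer matches the minus strand downstream
within a product-size cap, in both pair orientations.  Matching is exact
full-length by default (the strictest reading of "default matching
parameters"); a Hamming-mismatch tolerance is a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import GenomicInterval, NovtxError, TranscriptModel
from .orfs import extract_spliced_sequence, reverse_complement

R_GAS = 1.987  # cal / (K mol)

# Breslauer 1986 nearest-neighbor stacks as used by the legacy oligotm code:
# enthalpy in units of -100 cal/mol, entropy in units of -0.1 cal/(K mol).
_BRESLAUER_DH = {
    "AA": 91, "AC": 65, "AG": 78, "AT": 86,
    "CA": 58, "CC": 110, "CG": 119, "CT": 78,
    "GA": 56, "GC": 111, "GG": 110, "GT": 65,
    "TA": 60, "TC": 56, "TG": 58, "TT": 91,
}
_BRESLAUER_DS = {
    "AA": 240, "AC": 173, "AG": 208, "AT": 239,
    "CA": 129, "CC": 266, "CG": 278, "CT": 208,
    "GA": 135, "GC": 267, "GG": 266, "GT": 173,
    "TA": 169, "TC": 135, "TG": 129, "TT": 240,
}
_INITIATION_DS = 108  # -10.8 e.u. in the same -0.1 cal/(K mol) units


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic settings for Tm calculation."""

    nn_table: str = "breslauer1986"
    salt_correction: str = "schildkraut"
    monovalent_mM: float = 50.0
    oligo_nM: float = 50.0

    def __post_init__(self) -> None:
        if self.monovalent_mM <= 0 or self.oligo_nM <= 0:
            raise ValueError("concentrations must be > 0")
        if self.nn_table not in ("breslauer1986", "santalucia1998"):
            raise ValueError(f"unknown nn_table {self.nn_table!r}")
        if self.salt_correction != "schildkraut":
            raise ValueError(f"unknown salt correction {self.salt_correction!r}")


DEFAULT_THERMO = ThermoParams()


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous/invalid bases {sorted(bad)} in primer {seq}")
    if len(seq) < 10:
        raise ValueError(f"primer shorter than 10 nt: {seq}")
    return seq


def primer_tm(seq: str, params: ThermoParams = DEFAULT_THERMO) -> float:
    """Nearest-neighbor melting temperature in degrees Celsius."""
    seq = _check_sequence(seq)
    if params.nn_table == "santalucia1998":
        from Bio.SeqUtils import MeltingTemp as mt

        return float(
            mt.Tm_NN(
                seq,
                nn_table=mt.DNA_NN3,
                Na=params.monovalent_mM,
                dnac1=params.oligo_nM,
                dnac2=0,
                saltcorr=1,
            )
        )
    dh = sum(_BRESLAUER_DH[seq[i : i + 2]] for i in range(len(seq) - 1))
    ds = sum(_BRESLAUER_DS[seq[i : i + 2]] for i in range(len(seq) - 1))
    ds += _INITIATION_DS
    delta_h = -dh * 100.0  # cal/mol
    delta_s = -ds * 0.1  # cal/(K mol)
    conc = params.oligo_nM * 1e-9 / 4.0
    tm_kelvin = delta_h / (delta_s + R_GAS * math.log(conc))
    return tm_kelvin - 273.15 + 16.6 * math.log10(params.monovalent_mM / 1000.0)


@dataclass(frozen=True)
class PrimerPair:
    """A validation-assay primer pair, both sequences written 5'->3'."""

    name: str
    forward: str
    reverse: str
    target_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _check_sequence(self.forward))
        object.__setattr__(self, "reverse", _check_sequence(self.reverse))


@dataclass(frozen=True)
class Amplicon:
    """One predicted PCR product on the genome."""

    interval: GenomicInterval
    forward_site: GenomicInterval
    reverse_site: GenomicInterval

    @property
    def product_size(self) -> int:
        return self.interval.length


def check_oligo_constraints(
    seq: str,
    len_window: tuple[int, int] = (18, 22),
    tm_window: tuple[float, float] = (57.0, 63.0),
    params: ThermoParams = DEFAULT_THERMO,
) -> list[str]:
    """Window violations for one primer (empty list means pass).

    Defaults encode the design targets 20 +/- 2 bp and 60 +/- 3 degC, both
    windows inclusive at their boundaries.
    """
    reasons = []
    n = len(seq)
    if not len_window[0] <= n <= len_window[1]:
        reasons.append(f"length {n} outside [{len_window[0]}, {len_window[1]}]")
    tm = primer_tm(seq, params)
    if not tm_window[0] <= tm <= tm_window[1]:
        reasons.append(
            f"Tm {tm:.2f} outside [{tm_window[0]:.1f}, {tm_window[1]:.1f}]"
        )
    return reasons


def check_primer_constraints(
    pair: PrimerPair,
    len_window: tuple[int, int] = (18, 22),
    tm_window: tuple[float, float] = (57.0, 63.0),
    params: ThermoParams = DEFAULT_THERMO,
) -> tuple[bool, list[str]]:
    """Both primers must sit inside both windows."""
    reasons = [
        f"forward: {r}" for r in check_oligo_constraints(pair.forward, len_window, tm_window, params)
    ] + [
        f"reverse: {r}" for r in check_oligo_constraints(pair.reverse, len_window, tm_window, params)
    ]
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# in-silico PCR


def _find_sites(haystack: str, needle: str, max_mismatches: int) -> list[int]:
    """0-based start positions where ``needle`` matches ``haystack`` with at
    most ``max_mismatches`` Hamming mismatches."""
    n, m = len(haystack), len(needle)
    if m == 0 or m > n:
        return []
    if max_mismatches == 0:
        sites = []
        pos = haystack.find(needle)
        while pos != -1:
            sites.append(pos)
            pos = haystack.find(needle, pos + 1)
        return sites
    sites = []
    for i in range(n - m + 1):
        mism = 0
        window = haystack[i : i + m]
        for a, b in zip(window, needle):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            sites.append(i)
    return sites


def insilico_pcr(
    genome: Mapping[str, str],
    pair: PrimerPair,
    max_product: int,
    max_mismatches: int = 0,
) -> list[Amplicon]:
    """Enumerate all products of ``pair`` on ``genome`` up to ``max_product``.

    Both orientations are searched (either primer may prime the plus strand),
    so the output is invariant under swapping the order of the pair.
    Identical product intervals found in both orientations are reported once.
    """
    if max_product <= 0:
        raise ValueError("max_product must be > 0")
    amplicons: dict[tuple[str, int, int], Amplicon] = {}
    orientations = [(pair.forward, pair.reverse), (pair.reverse, pair.forward)]
    for chrom in sorted(genome):
        seq = str(genome[chrom]).upper()
        for plus_primer, minus_primer in orientations:
            plus_sites = _find_sites(seq, plus_primer, max_mismatches)
            minus_sites = _find_sites(seq, reverse_complement(minus_primer), max_mismatches)
            if not plus_sites or not minus_sites:
                continue
            lp, lm = len(plus_primer), len(minus_primer)
            for i in plus_sites:
                for j in minus_sites:
                    if j < i:
                        continue
                    size = j + lm - i
                    if size > max_product or size < max(lp, lm):
                        continue
                    start, end = i + 1, j + lm  # to 1-based inclusive
                    key = (chrom, start, end)
                    if key not in amplicons:
                        amplicons[key] = Amplicon(
                            interval=GenomicInterval(chrom, start, end),
                            forward_site=GenomicInterval(chrom, i + 1, i + lp, "+"),
                            reverse_site=GenomicInterval(chrom, j + 1, j + lm, "-"),
                        )
    return [amplicons[k] for k in sorted(amplicons)]


def assess_specificity(
    amplicons: Sequence[Amplicon], target: GenomicInterval
) -> bool:
    """Specific iff at least one product exists and every product overlaps
    the targeted genomic interval."""
    if not amplicons:
        return False
    return all(a.interval.overlaps(target) for a in amplicons)


def amplicon_spans_all_exons(
    model: TranscriptModel,
    pair: PrimerPair,
    genome=None,
    spliced_seq: str | None = None,
) -> tuple[bool, str | None]:
    """Does the pair's spliced-coordinate amplicon touch every exon?

    Locates the forward primer and the reverse complement of the reverse
    primer on the model's spliced sequence; the amplicon spans from the
    forward site to the reverse site.  Returns ``(ok, reason)`` where a
    failed primer placement yields ``(False, reason)``.
    """
    if spliced_seq is None:
        if genome is None:
            raise ValueError("provide genome or spliced_seq")
        spliced_seq = extract_spliced_sequence(genome, model)
    spliced_seq = spliced_seq.upper()
    f = spliced_seq.find(pair.forward)
    if f == -1:
        return (False, "forward primer not found on spliced sequence")
    rc = reverse_complement(pair.reverse)
    r = spliced_seq.rfind(rc)
    if r == -1:
        return (False, "reverse primer not found on spliced sequence")
    amp_start, amp_end = f, r + len(rc) - 1  # 0-based spliced coords
    if amp_end < amp_start:
        return (False, "reverse site upstream of forward site")
    # exon blocks in spliced (transcription-order) coordinates
    exon_lengths = [e.length for e in model.exons]
    if model.strand == "-":
        exon_lengths = exon_lengths[::-1]
    pos = 0
    for k, length in enumerate(exon_lengths, 1):
        block_start, block_end = pos, pos + length - 1
        if amp_start > block_end or amp_end < block_start:
            return (False, f"amplicon misses exon block {k}")
        pos += length
    return (True, None)
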