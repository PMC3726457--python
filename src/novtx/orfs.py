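"""Spliced-sequence extraction, six-frame translation and the 50-aa ORF rule.

A candidate's coding potential is screened by translating its spliced
sequence in all six reading frames and measuring the longest stop-free
peptide run.  An ORF here is a stop-to-stop segment (frame ends count as
boundaries); by default no initiator methionine is required, matching the
"longest calculated peptide" reading of the upstream design, with an
ATG-anchored mode available behind a flag.  Codons containing N translate to
'X', and 'X' does not break a run (unknown is not a stop).
"""

from __future__ import annotations

from typing import Iterable

from Bio.Data import CodonTable

from .core import NovtxError, TranscriptModel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in _STANDARD.stop_codons})

FRAMES = (1, 2, 3, -1, -2, -3)


class SequenceExtractionError(NovtxError):
    """An exon lies outside its chromosome sequence."""


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def _chrom_sequence(genome, chrom: str):
    """Accept dict-of-str or a pyfaidx.Fasta-like mapping."""
    try:
        return genome[chrom]
    except KeyError as exc:
        raise SequenceExtractionError(f"chromosome {chrom!r} not in genome") from exc


def extract_spliced_sequence(genome, model: TranscriptModel) -> str:
    """Concatenate exon sequences in transcription order.

    Exons are read off the forward strand left to right and the concatenation
    is reverse-complemented as a whole for minus-strand models, so the result
    always reads 5'->3' in the transcript's own orientation.  ``genome`` may
    be a plain ``{chrom: sequence}`` dict or a ``pyfaidx.Fasta``.
    """
    chrom_seq = _chrom_sequence(genome, model.chrom)
    chrom_len = len(chrom_seq)
    parts = []
    for i, exon in enumerate(model.exons, 1):
        if exon.end > chrom_len:
            raise SequenceExtractionError(
                f"transcript {model.id} exon {i} ({exon}) exceeds "
                f"chromosome length {chrom_len}"
            )
        piece = chrom_seq[exon.start - 1 : exon.end]
        parts.append(str(piece).upper())
    spliced = "".join(parts)
    if model.strand == "-":
        spliced = reverse_complement(spliced)
    return spliced


def translate_frame(dna: str) -> str:
    """Translate one forward frame; trailing partial codon dropped."""
    dna = dna.upper()
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def six_frame_translate(dna: str) -> dict[int, str]:
    """Translations keyed by frame: +1..+3 off the sequence, -1..-3 off its
    reverse complement.  Stops are ``*``; an empty input gives six empty
    strings."""
    rc = reverse_complement(dna)
    return {
        1: translate_frame(dna),
        2: translate_frame(dna[1:]),
        3: translate_frame(dna[2:]),
        -1: translate_frame(rc),
        -2: translate_frame(rc[1:]),
        -3: translate_frame(rc[2:]),
    }


def _longest_run(peptide: str, require_start: bool) -> int:
    best = 0
    for segment in peptide.split("*"):
        if require_start:
            pos = segment.find("M")
            length = len(segment) - pos if pos >= 0 else 0
        else:
            length = len(segment)
        best = max(best, length)
    return best


def longest_orf_length(dna: str, require_start: bool = False) -> int:
    """Length (residues) of the longest stop-free peptide run over all six
    frames.  With ``require_start=True`` runs are anchored at their first
    methionine."""
    return max(
        _longest_run(pep, require_start) for pep in six_frame_translate(dna).values()
    )


def orf_filter(
    models: Iterable[TranscriptModel],
    genome,
    min_aa: int = 50,
    require_start: bool = False,
) -> list[TranscriptModel]:
    """Keep models whose longest predicted peptide is >= ``min_aa`` residues."""
    kept = []
    for m in models:
        seq = extract_spliced_sequence(genome, m)
        if longest_orf_length(seq, require_start=require_start) >= min_aa:
            kept.append(m)
    return kept
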