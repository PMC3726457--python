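"""Primer QC and in-silico PCR specificity.

Melting temperatures use the legacy nearest-neighbor defaults (Breslauer
stacks, Schildkraut-Lifson salt correction, 50 mM Na+, 50 nM oligo); design
windows are 20 +/- 2 bp and 60 +/- 3 degC.  In-silico PCR enumerates every
product under a size cap and accepts a pair as specific only if all its
products overlap the targeted locus.
"""

from novtx import (
    GenomicInterval,
    PrimerPair,
    assess_specificity,
    check_primer_constraints,
    insilico_pcr,
    primer_tm,
    reverse_complement,
)

fwd, rev = "TGAGAAGGAAGCCAAGGAAA", "GCCTTGACCTTTTCAGCAAG"
print(f"Tm(forward) = {primer_tm(fwd):.2f} degC")
print(f"Tm(reverse) = {primer_tm(rev):.2f} degC")

pair = PrimerPair("demo", fwd, rev)
ok, reasons = check_primer_constraints(pair)
print(f"constraint check: {'pass' if ok else reasons}")

# a toy genome with one planted amplification site 500 bp long
genome = {"chr1": "T" * 1000 + fwd + "A" * 460 + reverse_complement(rev) + "T" * 1000}
amplicons = insilico_pcr(genome, pair, max_product=1000)
for a in amplicons:
    print(f"amplicon {a.interval}  product {a.product_size} bp")
target = GenomicInterval("chr1", 900, 1700)
print("specific for chr1:900-1700:", assess_specificity(amplicons, target))
# One product of the expected size that overlaps the target -> the pair
# would be accepted for expression validation.
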