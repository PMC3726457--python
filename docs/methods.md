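# Methods

## Scope and model

`novtx` triages transcript models assembled from RNA-seq in regions without
gene annotation.  The pipeline is a chain of per-transcript decision rules;
nothing is fit or trained.  Upstream steps — read alignment, splice-junction
calling, expression normalization, and the homology search itself — are out
of scope: their tabular outputs are inputs here.

Coordinates are 1-based fully inclusive at every interface.  Distance
between intervals is the count of bases strictly between them; overlap and
direct abutment are distance 0.  Strand is carried on every record but
ignored for overlap and distance (the intergenic-distance filter is
strand-blind).  Depth is one scalar per transcript, read from the evidence
sidecar; it is interpreted as the minimum exon coverage, but since it is
supplied rather than computed, any per-model summary the caller prefers can
be used.

## The prioritization cascade

Four filters, all thresholds inclusive, applied iteratively (the order
affects only the per-stage counts — each filter is an independent predicate,
so the final set is order-invariant, which the suite verifies):

| filter | default | unit | note |
|---|---|---|---|
| depth | ≥ 30 | reads | scalar per model |
| intergenic distance | ≥ 5,000 | bp | vs. nearest annotated gene/pseudogene on the same chromosome |
| exon count | ≥ 3 | exons | |
| tissue restriction | max Z > G(N, α) | — | α = 0.05, N = tissue count |

**Tissue restriction.**  For each transcript, per-tissue normalized values
are standardized with the sample (n−1) deviation and the *maximum signed*
Z-score is compared to the two-sided Grubbs/ESD critical value
G = ((N−1)/√N)·√(t²/(N−2+t²)), t the upper α/(2N) t-quantile with N−2 df.
G(8, 0.05) = 2.1266 ≈ 2.13.  Three deliberate choices:

- only *over*-expression flags a transcript (restriction-by-absence gives a
  large negative Z and is ignored);
- the test is one-shot (a single deviant tissue), not an iterated ESD with
  multiple removals;
- the two-sided critical value is used even though the flag is upper-tailed,
  because that is the classical tabulated value (the one-sided bound at
  N = 8 would be ≈ 2.03).

A consequence worth knowing: under the test's own normality assumption the
upper-tail flag at the two-sided critical value has size ≈ α/2, and on
skewed (e.g. log-normal) expression backgrounds the false-positive rate is
substantially *above* α — 0.17 at σ_log = 0.5 in our measurements.  The
statistic is also bounded by (N−1)/√N (2.4749 at N = 8), so no single
outlier can exceed that, however extreme.  Zero-variance rows are not
testable and are excluded with a logged reason.

## ORF screen

The spliced sequence (exon concatenation, reverse-complemented as a whole on
the minus strand) is translated in six frames with the standard code.  An
ORF is a stop-free peptide run; frame ends count as boundaries and no
initiator methionine is required by default (`require_start=True` anchors
runs at their first Met).  Codons containing N translate to `X`, and `X`
does not terminate a run — unknown is not a stop, which is conservative
toward keeping candidates.  The default threshold is 50 residues.

## Homology triage

Queries partition into three categories.  `annotated_gene` requires one hit
satisfying all of: e-value ≤ 1e-5, bit score ≥ 100, subject flagged as an
annotated transcribed gene.  The flag is an input column; a regex helper
over subject descriptions exists for convenience but is deliberately not
authoritative.  Percentages are reported to the nearest integer with
half-up rounding.

## Primer validation

Tm uses the nearest-neighbor model with the legacy design-tool defaults:
Breslauer (1986) ΔH/ΔS stacks, helix-initiation entropy −10.8 cal/(K·mol),
Tm = ΔH/(ΔS + R ln(C/4)) − 273.15, Schildkraut–Lifson salt correction
16.6·log₁₀[Na⁺], at 50 mM monovalent salt and 50 nM annealing oligo.  These
settings reproduce published assay primers' printed Tm values to 0.01 °C; a
SantaLucia (1998) mode (via biopython) is available because modern designs
use it, and the two differ by ~3 °C on typical 20-mers.  Constraint windows
default to 20 ± 2 bp and 60 ± 3 °C, inclusive at the boundaries.

In-silico PCR enumerates sites where one primer matches the plus strand and
the other's reverse complement lies downstream within the product-size cap;
both pair orientations are searched, and duplicate product intervals are
reported once.  Matching is exact and full-length by default — the strictest
reading of a web tool's "default matching parameters", which actually permit
some non-3′-anchored mismatching; a Hamming-mismatch tolerance parameter is
provided for sensitivity analyses.  Specificity is accepted only when at
least one product exists *and* every product overlaps the target locus.  The
exon-spanning check locates both primers on the spliced sequence and
requires the spliced amplicon to touch ≥ 1 base of every exon.

## Synteny contexts

A context grows symmetrically from the candidate locus to ~1 Mb, then each
edge extends outward to wholly include the nearest gene, so both ends are
anchored by annotated genes; hitting a chromosome end first flags the
context partial.  Conserved synteny is the percent of *all* genes in the
window (not only testable ones) whose ortholog lies on the modal target
chromosome — untestable genes count against conservation, matching a
homologous-gene-pairs-over-predicted-genes reading.  Inversion is reduced to
the sign of Kendall's τ between source and target gene order on the modal
chromosome (≥ 3 pairs required; segmental inversions show as intermediate τ
but are not called).  Alignment coverage is the percent of the window
covered by the union of alignment blocks; an identity-weighted variant was
considered and rejected because block identities are not always available —
coverage-of-interval is the documented meaning of the conservation percent
here.

## Synthetic cohorts

The generator plants outcomes by construction rather than rejection at the
cohort level, so stage tests are deterministic:

- **Depth / distance / exon draws** come from truncated log-normals and a
  three-component log-normal distance mixture (centers 1 kb / 20 kb /
  200 kb, weights 0.65 / 0.25 / 0.10, σ_log = 0.5 — only the peak locations
  are constrained by the emulated cohort; weights and spread were chosen
  once to make the 1 kb peak dominant and are not tuned).  Labels are then
  *derived* from the drawn values, so truth and data cannot disagree.
  Values are resampled, not clipped, into the published ranges
  (74–10,401 bp, 19–3,042 reads, 2–9 exons with ~62% two-exon models to fix
  the median at 2).
- **Layout**: chromosomes are tiled as gene — planted gap — transcript —
  larger gap — next gene, so each transcript's nearest-feature distance is
  exactly its planted gap.  A closing anchor gene bounds each chromosome.
  Decoy models overlapping genes exercise the novelty screen.
- **Expression**: background rows are i.i.d. log-normal (σ_log = 0.5).
  Restricted rows boost one tissue to hit a planted Grubbs Z of 2.40
  (solved numerically; the statistic's upper bound at 8 tissues is 2.4749,
  so targets at or above that bound are infeasible and rejected).  Background rows in
  labeled cohorts are nudged below Z = 2.0 so planted-negative labels are
  exact; an `enforce_labels=False` mode leaves the background untouched for
  false-positive-rate studies.
- **ORF content** is spliced into the emitted genome: pass-labeled
  transcripts carry a designed stop-free codon run (50–120 codons);
  fail-labeled transcripts are stamped every 100 bp with a 12-mer that
  contains a TAA in all three frame phases and is its own reverse
  complement, bounding every six-frame run well below 50 residues.
- **Homology tables** emit hits that reproduce each planted category under
  the classifier (exact counts 197/55/176 under the paper preset,
  multinomial otherwise).
- **Synteny contexts** plant gene count (19–25), conserved fraction,
  whole-window inversion, flank-null islands, and exact block coverage.

What the generator does *not* emulate: read-level noise, assembly artifacts,
mappability, correlated expression across tissues, paralogy structure in hit
tables, or real genome composition (sequence is uniform random at GC 0.5).
Passing stage tests therefore demonstrates correctness of the decision
rules, not robustness to upstream noise.

## Pipeline and reproducibility

Stages communicate via files (GTF/TSV/FASTA) so each is independently
re-runnable; every count in the final report is recomputable from the
archived intermediates, and the suite audits this.  Reports carry a config
hash and package version but no wall-clock timestamp, so a rerun with an
identical config is byte-identical.  Exit codes: 0 success, 2 validation
failure, 3 stage failure.  All randomness flows from a single integer seed
through split generators per component.

Problem sizes in the shipped tests were chosen to keep the full suite
comfortable on one CPU: the planted-cohort recovery check runs the complete
428-transcript workflow (with genome emission) across 100 seeds; oracle
equivalence suites use 500 interval layouts, 150 random 400-mers, 20 planted
genomes, 100 block sets, and every gene-order permutation up to n = 6.

## Known limitations

- The depth filter trusts the supplied per-model scalar; no recomputation
  from alignments.
- The outlier test's size is miscalibrated on skewed backgrounds (see
  above); on real normalized expression the tissue-restriction stage should
  be read as a ranking heuristic, not a calibrated α-level test.
- In-silico PCR is exact-match by default and does not model 3′-mismatch
  tolerance, secondary structure, or dimers.
- Inversion calling is whole-window only; segmental rearrangements are
  visible in τ's magnitude but not called.
- The subject-annotation flag of hit tables must be produced upstream;
  free-text classification is heuristic.
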