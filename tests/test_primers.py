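"""Nearest-neighbor Tm, primer constraint windows, in-silico PCR."""

import numpy as np
import pytest
from scipy import stats

from novtx import (
    GenomicInterval,
    PrimerPair,
    ThermoParams,
    amplicon_spans_all_exons,
    assess_specificity,
    check_oligo_constraints,
    check_primer_constraints,
    insilico_pcr,
    primer_tm,
    reverse_complement,
)

from conftest import TABLE1_PRIMERS, make_model
from oracles import brute_pcr_products


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestPrimerTm:
    @pytest.mark.parametrize(
        "seq,expected", [(seq, tm) for _t, _r, seq, _l, tm in TABLE1_PRIMERS],
        ids=[f"{t}_{r}" for t, r, *_ in TABLE1_PRIMERS],
    )
    def test_published_assay_primers(self, seq, expected):
        assert primer_tm(seq) == pytest.approx(expected, abs=0.05)

    def test_duplex_symmetry(self, rng):
        for _ in range(50):
            seq = random_dna(rng, 20)
            assert primer_tm(seq) == pytest.approx(
                primer_tm(reverse_complement(seq)), abs=1e-9
            )

    def test_gc_content_trend(self, rng):
        seqs = [random_dna(rng, 20) for _ in range(250)]
        gc = [s.count("G") + s.count("C") for s in seqs]
        tm = [primer_tm(s) for s in seqs]
        rho, _ = stats.spearmanr(gc, tm)
        assert rho > 0.8

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            primer_tm("ACGTACGTACGTACGTACGN")

    def test_santalucia_mode_differs_but_is_sane(self):
        seq = "TGAGAAGGAAGCCAAGGAAA"
        alt = primer_tm(seq, ThermoParams(nn_table="santalucia1998"))
        assert 40 < alt < 75
        assert alt != pytest.approx(primer_tm(seq), abs=0.2)


class TestConstraints:
    def test_all_published_primers_pass(self):
        for transcript, role, seq, _length, _tm in TABLE1_PRIMERS:
            assert check_oligo_constraints(seq) == [], f"{transcript} {role}"

    def test_length_window(self):
        assert any("length" in r for r in check_oligo_constraints("A" * 10 + "CGT" * 5))

    def test_tm_window_boundary(self):
        # an AT-rich 20-mer melts below the inclusive 57.0 floor
        seq = "AATGGATTAGAGTCAATGAC"
        assert primer_tm(seq) < 57.0
        assert any("Tm" in r for r in check_oligo_constraints(seq))

    def test_pair_reports_both_sides(self):
        pair = PrimerPair("p", "A" * 25, "TGAGAAGGAAGCCAAGGAAA")
        ok, reasons = check_primer_constraints(pair)
        assert not ok
        assert any(r.startswith("forward") for r in reasons)
        assert not any(r.startswith("reverse") for r in reasons)


def plant_site(genome, chrom, pos, seq):
    s = genome[chrom]
    genome[chrom] = s[: pos - 1] + seq + s[pos - 1 + len(seq) :]


class TestInsilicoPcr:
    def make_genome(self, rng, n=5000):
        return {"chr1": random_dna(rng, n)}

    def test_single_planted_site_pair(self, rng):
        genome = self.make_genome(rng)
        fwd, rev = "TGAGAAGGAAGCCAAGGAAA", "GCCTTGACCTTTTCAGCAAG"
        plant_site(genome, "chr1", 1001, fwd)
        plant_site(genome, "chr1", 1481, reverse_complement(rev))
        pair = PrimerPair("p", fwd, rev)
        amps = insilico_pcr(genome, pair, max_product=1000)
        assert len(amps) == 1
        assert amps[0].product_size == 500
        assert (amps[0].interval.start, amps[0].interval.end) == (1001, 1500)
        # a tighter cap excludes the product
        assert insilico_pcr(genome, pair, max_product=400) == []

    def test_amplicon_count_monotone_in_product_cap(self, rng):
        genome = self.make_genome(rng)
        fwd, rev = "TGAGAAGGAAGCCAAGGAAA", "GCCTTGACCTTTTCAGCAAG"
        for pos in (101, 1001, 2001):
            plant_site(genome, "chr1", pos, fwd)
        for pos in (601, 1501, 3001):
            plant_site(genome, "chr1", pos, reverse_complement(rev))
        pair = PrimerPair("p", fwd, rev)
        counts = [len(insilico_pcr(genome, pair, max_product=cap))
                  for cap in (200, 600, 1200, 3500, 10_000)]
        assert counts == sorted(counts)

    def test_pair_order_swap_is_invariant(self, rng):
        genome = self.make_genome(rng)
        fwd, rev = "TGAGAAGGAAGCCAAGGAAA", "GCCTTGACCTTTTCAGCAAG"
        plant_site(genome, "chr1", 501, fwd)
        plant_site(genome, "chr1", 901, reverse_complement(rev))
        a = insilico_pcr(genome, PrimerPair("p", fwd, rev), 2000)
        b = insilico_pcr(genome, PrimerPair("p", rev, fwd), 2000)
        key = lambda amps: {(x.interval.chrom, x.interval.start, x.interval.end) for x in amps}
        assert key(a) == key(b) != set()

    def test_strand_swap_mirrors_amplicons(self, rng):
        # reverse-complementing the template (so each primer anneals to the
        # other strand) maps every product to its mirrored coordinates
        genome = self.make_genome(rng)
        fwd, rev = "TGAGAAGGAAGCCAAGGAAA", "GCCTTGACCTTTTCAGCAAG"
        plant_site(genome, "chr1", 501, fwd)
        plant_site(genome, "chr1", 901, reverse_complement(rev))
        L = len(genome["chr1"])
        flipped = {"chr1": reverse_complement(genome["chr1"])}
        pair = PrimerPair("p", fwd, rev)
        a = insilico_pcr(genome, pair, 2000)
        b = insilico_pcr(flipped, pair, 2000)
        mirrored = {
            (x.interval.chrom, L - x.interval.end + 1, L - x.interval.start + 1)
            for x in b
        }
        assert mirrored == {
            (x.interval.chrom, x.interval.start, x.interval.end) for x in a
        } != set()

    def test_agrees_with_quadratic_enumeration(self, rng):
        fwd, rev = "ACGTGGTCAAGT", "TTGCAGGTCCAT"
        for trial in range(20):
            genome = {"chr1": random_dna(rng, 1500), "chr2": random_dna(rng, 800)}
            for _ in range(int(rng.integers(1, 5))):
                chrom = "chr1" if rng.random() < 0.7 else "chr2"
                pos = int(rng.integers(1, len(genome[chrom]) - 30))
                probe = [fwd, rev, reverse_complement(fwd), reverse_complement(rev)][
                    int(rng.integers(0, 4))
                ]
                plant_site(genome, chrom, pos, probe)
            cap = int(rng.integers(100, 1200))
            amps = insilico_pcr(genome, PrimerPair("p", fwd, rev), cap)
            got = {(a.interval.chrom, a.interval.start, a.interval.end) for a in amps}
            assert got == brute_pcr_products(genome, fwd, rev, cap)

    def test_mismatch_tolerance_is_monotone(self, rng):
        genome = self.make_genome(rng, 3000)
        fwd, rev = "TGAGAAGGAAGCCAAGGAAA", "GCCTTGACCTTTTCAGCAAG"
        mutated = "TGAGAAGGAAGCCAAGCAAA"  # one substitution
        plant_site(genome, "chr1", 501, mutated)
        plant_site(genome, "chr1", 901, reverse_complement(rev))
        pair = PrimerPair("p", fwd, rev)
        assert insilico_pcr(genome, pair, 2000, max_mismatches=0) == []
        assert len(insilico_pcr(genome, pair, 2000, max_mismatches=1)) == 1


class TestSpecificity:
    def amp(self, start, end):
        amps = insilico_pcr(
            {"c": "T" * (start - 1) + "TGAGAAGGAAGCCAAGGAAA"
             + "A" * (end - start + 1 - 40) + reverse_complement("GCCTTGACCTTTTCAGCAAG")
             + "T" * 50},
            PrimerPair("p", "TGAGAAGGAAGCCAAGGAAA", "GCCTTGACCTTTTCAGCAAG"),
            max_product=end - start + 1,
        )
        return amps

    def test_single_on_target_accepted(self):
        amps = self.amp(101, 400)
        target = GenomicInterval("c", 50, 500)
        assert assess_specificity(amps, target)

    def test_off_target_product_rejected(self):
        amps = self.amp(101, 400)
        off_target = GenomicInterval("c", 10_000, 10_500)
        assert not assess_specificity(amps, off_target)

    def test_no_products_rejected(self):
        assert not assess_specificity([], GenomicInterval("c", 1, 100))


class TestSpansAllExons:
    def build(self, rng):
        genome = {"chr1": random_dna(rng, 4000)}
        m = make_model("T", [(101, 400), (901, 1200), (2001, 2300)])
        return genome, m

    def test_terminal_exon_primers_span(self, rng):
        genome, m = self.build(rng)
        spliced = "".join(genome["chr1"][s - 1 : e] for s, e in
                          [(101, 400), (901, 1200), (2001, 2300)])
        fwd = spliced[10:30]
        rev = reverse_complement(spliced[-30:-10])
        ok, reason = amplicon_spans_all_exons(m, PrimerPair("p", fwd, rev), genome=genome)
        assert ok and reason is None

    def test_single_exon_placement_fails(self, rng):
        genome, m = self.build(rng)
        spliced = "".join(genome["chr1"][s - 1 : e] for s, e in
                          [(101, 400), (901, 1200), (2001, 2300)])
        # both primers inside the middle exon block (spliced 300..599)
        fwd = spliced[320:340]
        rev = reverse_complement(spliced[500:520])
        ok, reason = amplicon_spans_all_exons(m, PrimerPair("p", fwd, rev), genome=genome)
        assert not ok and "exon" in reason

    def test_unlocatable_primer_reports_reason(self, rng):
        genome, m = self.build(rng)
        ok, reason = amplicon_spans_all_exons(
            m, PrimerPair("p", "TGAGAAGGAAGCCAAGGAAA", "GCCTTGACCTTTTCAGCAAG"),
            genome=genome,
        )
        assert not ok and "not found" in reason

    def test_agrees_with_per_exon_containment(self, rng):
        genome, m = self.build(rng)
        blocks = [(0, 299), (300, 599), (600, 899)]
        spliced = "".join(genome["chr1"][s - 1 : e] for s, e in
                          [(101, 400), (901, 1200), (2001, 2300)])
        checked = 0
        for _ in range(150):
            a = int(rng.integers(0, 840))
            b = int(rng.integers(a + 20, 900))
            fwd = spliced[a : a + 20]
            rev_rc = spliced[b - 20 : b]
            if spliced.count(fwd) != 1 or spliced.count(rev_rc) != 1:
                continue  # multi-mapping primers would shift the located site
            ok, _ = amplicon_spans_all_exons(
                m, PrimerPair("p", fwd, reverse_complement(rev_rc)),
                spliced_seq=spliced,
            )
            start, end = a, b - 1
            expected = all(start <= be and end >= bs for bs, be in blocks)
            assert ok == expected
            checked += 1
        assert checked > 50
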