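"""Generator determinism, cohort shape, and planted-truth recovery."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from novtx import (
    GeneratorConfig,
    classify_homology,
    depth_filter,
    distance_filter,
    exon_filter,
    extract_spliced_sequence,
    generate_expression,
    generate_homology_table,
    generate_synteny_context,
    alignment_coverage_percent,
    conserved_synteny_fraction,
    detect_inversion,
    flank_conservation_profile,
    grubbs_statistic,
    longest_orf_length,
    nearest_feature_distance,
    paper_preset,
    simulate_cohort,
    tissue_restriction_filter,
)
from novtx.io import read_homology_tsv
from novtx.simulate import design_spliced_sequence

SMALL = GeneratorConfig(seed=3, n_transcripts=60, n_all_pass=6, n_overlapping_decoys=4)


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(SMALL)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = simulate_cohort(SMALL)
        b = simulate_cohort(SMALL)
        assert a.genome == b.genome
        assert a.truth.equals(b.truth)
        assert [(r.transcript_id, r.values) for r in a.expression] == [
            (r.transcript_id, r.values) for r in b.expression
        ]
        assert a.hits.equals(b.hits)

    def test_different_seed_differs(self):
        a = simulate_cohort(SMALL)
        b = simulate_cohort(dataclasses.replace(SMALL, seed=4))
        assert a.genome != b.genome


class TestGenomeSequence:
    def test_gc_fraction_near_half(self, small_cohort):
        seq = "".join(small_cohort.genome.values())[:1_000_000]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02

    def test_no_ambiguous_bases(self, small_cohort):
        chrom = next(iter(small_cohort.genome.values()))
        assert set(chrom) <= set("ACGT")


class TestCohortShape:
    def test_planted_labels_match_emitted_values(self, small_cohort):
        t = small_cohort.truth[small_cohort.truth.is_novel]
        cfg = small_cohort.config
        assert (t.passes_depth == (t.depth >= cfg.min_depth)).all()
        assert (t.passes_distance == (t.distance_bp >= cfg.min_distance)).all()
        assert (t.passes_exons == (t.n_exons >= cfg.min_exons)).all()

    def test_scalar_filters_recover_truth(self, small_cohort):
        cohort = small_cohort
        t = cohort.truth.set_index("transcript_id")
        novel = [m for m in cohort.models if t.loc[m.id, "is_novel"]]
        cfg = cohort.config
        assert {m.id for m in depth_filter(novel, cfg.min_depth)} == set(
            t[t.is_novel & t.passes_depth].index
        )
        assert {m.id for m in exon_filter(novel, cfg.min_exons)} == set(
            t[t.is_novel & t.passes_exons].index
        )
        assert {m.id for m in distance_filter(novel, cohort.annotation, cfg.min_distance)} == set(
            t[t.is_novel & t.passes_distance].index
        )

    def test_planted_distances_are_exact(self, small_cohort):
        cohort = small_cohort
        t = cohort.truth.set_index("transcript_id")
        for m in cohort.models:
            if not t.loc[m.id, "is_novel"]:
                continue
            assert nearest_feature_distance(m, cohort.annotation) == t.loc[m.id, "distance_bp"]

    def test_orf_labels_recovered_from_sequence(self, small_cohort):
        cohort = small_cohort
        t = cohort.truth.set_index("transcript_id")
        for m in cohort.models:
            if not t.loc[m.id, "is_novel"]:
                continue
            seq = extract_spliced_sequence(cohort.genome, m)
            assert (longest_orf_length(seq) >= cohort.config.min_orf_aa) == bool(
                t.loc[m.id, "passes_orf"]
            ), m.id

    def test_decoys_overlap_annotation(self, small_cohort):
        from novtx import overlaps_annotation

        t = small_cohort.truth.set_index("transcript_id")
        for m in small_cohort.models:
            assert overlaps_annotation(m, small_cohort.annotation) != bool(
                t.loc[m.id, "is_novel"]
            )


class TestOrfDesigner:
    @pytest.mark.parametrize("length,passes", [(180, True), (400, True), (400, False), (96, False)])
    def test_designed_sequences_honor_label(self, rng, length, passes):
        for _ in range(20):
            seq = design_spliced_sequence(rng, length, passes, min_orf_aa=50)
            assert len(seq) == length
            assert (longest_orf_length(seq) >= 50) == passes

    def test_too_short_for_pass_rejected(self, rng):
        with pytest.raises(ValueError):
            design_spliced_sequence(rng, 120, True, min_orf_aa=50)


class TestExpressionGenerator:
    def test_planted_rows_always_flagged(self, rng):
        cfg = dataclasses.replace(SMALL, seed=11)
        ids = [f"T{i}" for i in range(120)]
        restricted = {ids[i]: i % cfg.n_tissues for i in range(0, 120, 4)}
        rows, truth = generate_expression(cfg, ids, restricted=restricted, rng=rng)
        surviving, flagged = tissue_restriction_filter(rows, cfg.alpha)
        assert set(surviving) == set(restricted)
        # sensitivity is 1 by construction; the boosted tissue is the flagged one
        tissues = rows[0].tissue_names
        for tid, t_idx in restricted.items():
            assert flagged[tid] == tissues[t_idx]

    def test_planted_z_hits_target(self, rng):
        cfg = dataclasses.replace(SMALL, seed=12)
        rows, _ = generate_expression(cfg, ["a"], restricted={"a": 3}, rng=rng)
        max_z, idx = grubbs_statistic(rows[0].values)
        assert idx == 3
        assert max_z == pytest.approx(cfg.restricted_target_z, abs=1e-6)

    def test_unrestricted_rows_never_flagged_when_enforced(self, rng):
        cfg = dataclasses.replace(SMALL, seed=13)
        rows, _ = generate_expression(cfg, [f"T{i}" for i in range(500)], rng=rng)
        surviving, _ = tissue_restriction_filter(rows, cfg.alpha)
        assert surviving == []

    def test_unenforced_background_has_positive_flag_rate(self, rng):
        cfg = dataclasses.replace(SMALL, seed=14)
        rows, _ = generate_expression(
            cfg, [f"T{i}" for i in range(2000)], rng=rng, enforce_labels=False
        )
        surviving, _ = tissue_restriction_filter(rows, cfg.alpha)
        assert len(surviving) > 0


class TestHomologyGenerator:
    def test_classifier_recovery_is_exact(self, rng):
        cfg = dataclasses.replace(SMALL, seed=21)
        ids = [f"T{i}" for i in range(150)]
        df, truth = generate_homology_table(cfg, ids, rng=rng)
        import io

        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        hits = read_homology_tsv(buf)
        cats = classify_homology(hits, ids)
        assert {q: c.value for q, c in cats.items()} == truth.to_dict()

    def test_exact_counts_mode(self, rng):
        cfg = dataclasses.replace(SMALL, n_transcripts=428,
                                  homology_exact_counts=(197, 55, 176))
        ids = [f"T{i}" for i in range(428)]
        _df, truth = generate_homology_table(cfg, ids, rng=rng)
        counts = truth.value_counts()
        assert counts["annotated_gene"] == 197
        assert counts["unannotated_or_below_threshold"] == 55
        assert counts["no_alignment"] == 176

    def test_all_no_hit_config(self, rng):
        cfg = dataclasses.replace(SMALL, homology_proportions=(0.0, 0.0, 1.0),
                                  homology_exact_counts=None)
        ids = [f"T{i}" for i in range(30)]
        df, truth = generate_homology_table(cfg, ids, rng=rng)
        assert df.empty
        assert (truth == "no_alignment").all()


class TestSyntenyGenerator:
    def test_planted_fraction_and_inversion(self, rng):
        cfg = GeneratorConfig(seed=31)
        ctx, truth = generate_synteny_context(
            cfg, rng, n_genes=20, synteny_percent=75, inversion=True
        )
        assert conserved_synteny_fraction(ctx, "human") == truth["synteny_fraction"] == 75
        assert detect_inversion(ctx, "human") is True

    def test_planted_coverage_is_exact(self, rng):
        cfg = GeneratorConfig(seed=32)
        ctx, truth = generate_synteny_context(cfg, rng, coverage_percent=73.0)
        got = alignment_coverage_percent(ctx, "human")
        assert got == pytest.approx(truth["coverage_percent"])
        assert got == pytest.approx(73.0, abs=0.01)

    def test_no_orthologs_config(self, rng):
        cfg = GeneratorConfig(seed=33)
        ctx, _ = generate_synteny_context(cfg, rng, synteny_percent=0)
        assert conserved_synteny_fraction(ctx, "human") == 0

    def test_gene_count_in_study_range(self, rng):
        for _ in range(10):
            ctx, truth = generate_synteny_context(GeneratorConfig(seed=34), rng)
            assert 19 <= ctx.n_genes <= 25

    def test_flank_null_island(self, rng):
        cfg = GeneratorConfig(seed=35)
        ctx, truth = generate_synteny_context(cfg, rng, n_genes=20, flank_null=2)
        profile = flank_conservation_profile(ctx, "human", k=2)
        assert all(not f.has_ortholog for f in profile)
        assert len(truth["flank_null_ids"]) == 4


class TestDistanceMixture:
    def test_trimodal_modes_near_planted_centers(self):
        cohort = simulate_cohort(paper_preset(seed=5), with_sequence=False)
        d = cohort.truth[cohort.truth.is_novel].distance_bp.to_numpy(dtype=float)
        assert len(d) == 428
        logs = np.log10(d)
        hist, edges = np.histogram(logs, bins=24, range=(1.5, 6.0))
        centers = 10 ** ((edges[:-1] + edges[1:]) / 2)
        # local maxima of the smoothed histogram
        smooth = np.convolve(hist, [1, 2, 1], mode="same")
        modes = [
            centers[i]
            for i in range(1, len(smooth) - 1)
            if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 3
        ]
        for target in (1000, 20_000, 200_000):
            assert any(0.75 * target <= m <= 1.25 * target for m in modes), (
                target, modes,
            )
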