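"""Conserved synteny around a candidate locus.

An anchored ~1 Mb window is planted with 20 genes, 75% conserved synteny, a
whole-interval inversion, and alignment blocks covering exactly 73% of the
window — then each metric is recomputed from the context.
"""

from novtx import (
    GeneratorConfig,
    alignment_coverage_percent,
    conserved_synteny_fraction,
    detect_inversion,
    flank_conservation_profile,
    gene_order_tau,
    generate_synteny_context,
)

ctx, truth = generate_synteny_context(
    GeneratorConfig(seed=42),
    n_genes=20,
    synteny_percent=75,
    inversion=True,
    coverage_percent=73.0,
)

print(f"context {ctx.interval} holds {ctx.n_genes} genes")
print(f"conserved synteny: {conserved_synteny_fraction(ctx, 'human')}% "
      f"(planted {truth['synteny_fraction']}%)")
print(f"gene-order tau: {gene_order_tau(ctx, 'human'):+.2f} -> inversion: "
      f"{detect_inversion(ctx, 'human')}")
print(f"alignment coverage: {alignment_coverage_percent(ctx, 'human'):.2f}% "
      f"(planted {truth['coverage_percent']:.2f}%)")
for f in flank_conservation_profile(ctx, "human", k=2):
    print(f"  {f.side} #{f.rank} {f.gene_id}: ortholog={f.has_ortholog}, "
          f"syntenic={f.on_modal_chromosome}")
# A negative tau calls the planted whole-window inversion; the flank profile
# shows whether the genes nearest the candidate keep their orthologs.
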