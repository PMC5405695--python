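"""Relate the mark to expression and test GO-term enrichment of targets.

H3K27me3 targets are significantly less expressed than non-targets in
both genes and repeats (equal-variance Student t-test), and the target
set is enriched for the intein/protein-splicing GO term carried by the
subtelomeric upstream-archetype genes.
"""

from merochip import (
    PipelineConfig,
    SimulationParams,
    annotation_coverage,
    class_expression_comparison,
    enrich_all,
    group_expression_comparison,
    simulate_study,
)

cfg = PipelineConfig()
bundle = simulate_study(SimulationParams(seed=42))
targets = bundle.truth.target_genes | bundle.truth.target_repeats

out = group_expression_comparison(targets, bundle.features, bundle.fpkm)
for cls, r in out.items():
    print(f"{cls:7s}: target FPKM {r['mean_target']:6.2f} vs "
          f"non-target {r['mean_nontarget']:6.2f}  (t={r['t']:.2f}, p={r['p']:.2e})")
classes = class_expression_comparison(bundle.features, bundle.fpkm)
print(f"class means: genes {classes['gene']['mean']:.2f}, "
      f"repeats {classes['repeat']['mean']:.2f}")

gene_ids = {f.locus_id for f in bundle.gene_features}
cov = annotation_coverage(gene_ids, bundle.go_map)
print(f"\nGO coverage of the reference: {cov['n_annotated']}/{cov['n_total']} "
      f"({cov['pct']}%)")
rows = enrich_all(bundle.truth.target_genes, gene_ids, bundle.go_map, cfg)
print("enriched GO terms (Fisher + Benjamini-Yekutieli, min 5 entries):")
for r in rows:
    flag = "*" if r.significant else " "
    print(f" {flag} {r.term_id} {r.term_name:38s} "
          f"{r.n_target_with_term}/{r.n_target} vs {r.n_ref_with_term}/{r.n_ref} "
          f"adj p={r.p_adjusted:.2e}")
# Lower target expression in both classes reproduces the silencing-mark
# pattern; the starred protein-splicing term is the planted enrichment.
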