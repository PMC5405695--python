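"""Detect H3K27me3 domain enrichment at chromosome ends.

Peaks pooled across replicates are merged into domains (gap <= 500 bp);
an end counts as enriched when a domain supported by >= 2 replicates lies
within 2 kb. The generator plants terminal domains at 36 of 40 ends and
puts the nearest domain 4-5 kb away at the remaining four.
"""

from merochip import PipelineConfig, SimulationParams, chromosome_end_report, simulate_study

bundle = simulate_study(SimulationParams(seed=42))
report = chromosome_end_report(bundle.peaks, bundle.genome, PipelineConfig())

print(f"enriched ends: {report['n_enriched']} of {report['n_total']}")
misses = report["per_end"][~report["per_end"]["enriched"]]
print("non-enriched ends and their nearest-domain distances:")
for row in misses.itertuples():
    print(f"  {row.chrom} {row.end}: {row.distance_bp} bp")
# The four rejected ends sit just outside the 2 kb cut-off (their closest
# domain is 4-5 kb away) -- the same pattern the cut-off is built to
# distinguish from genuinely terminal telomere/subtelomere domains.
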