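"""Generate the default synthetic H3K27me3 study and look at its shape.

The generator plants everything the downstream analysis is meant to find:
marked genes and repeats with distinct enrichment archetypes, terminal
domains on 36 of 40 chromosome ends, hidden genes missing from the
annotation, and a GO vocabulary with an over-represented protein-splicing
term.
"""

from merochip import SimulationParams, simulate_study, write_study

bundle = simulate_study(SimulationParams(seed=42))

print(f"chromosomes      : {len(bundle.genome.chromosomes)}")
print(f"genome length    : {bundle.genome.total_length / 1e6:.1f} Mb")
print(f"genes / repeats  : {len(bundle.gene_features)} / {len(bundle.repeat_features)}")
print(f"marked genes     : {len(bundle.truth.target_genes)} "
      f"({100 * len(bundle.truth.target_genes) / len(bundle.gene_features):.0f}%)")
print(f"marked repeats   : {len(bundle.truth.target_repeats)} "
      f"({100 * len(bundle.truth.target_repeats) / len(bundle.repeat_features):.0f}%)")
print(f"enriched ends    : {len(bundle.truth.enriched_ends)} of "
      f"{2 * len(bundle.genome.chromosomes)}")
print(f"hidden genes     : {len(bundle.truth.hidden_genes)}")
print(f"peaks per rep    : {[len(p) for p in bundle.peaks.values()]}")

manifest = write_study(bundle, "scratch/example_study")
print(f"\nwrote {len(manifest)} files to scratch/example_study/")
# The counts above are the planted truth; every later example re-derives
# them from the emitted tracks and peak calls alone.
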