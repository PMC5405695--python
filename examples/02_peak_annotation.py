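"""Annotate peaks against the reference and call the consensus target set.

Each peak is matched to the locus whose length it covers best; peaks
covering at least 50% of a locus are high-overlap annotations. After
per-replicate deduplication, a locus called in at least 2 of 3 replicates
is a consensus H3K27me3 target.
"""

from collections import Counter

from merochip import (
    SimulationParams,
    categorize_peaks,
    consensus_targets,
    dedupe_targets,
    simulate_study,
    target_composition,
)

bundle = simulate_study(SimulationParams(seed=42))

replicate_sets = []
for rep in sorted(bundle.peaks):
    annotated = categorize_peaks(bundle.peaks[rep], bundle.features, threshold=0.5)
    counts = Counter(a.category for a in annotated)
    print(f"{rep}: {dict(counts)}")
    replicate_sets.append(dedupe_targets(annotated))

consensus = consensus_targets(replicate_sets, min_replicates=2)
comp = target_composition(consensus, bundle.features)
print(f"\nconsensus targets: {len(consensus)}")
print(f"genes  : {comp['n_genes']} ({comp['pct_genes']}% of all genes)")
print(f"repeats: {comp['n_repeats']} ({comp['pct_repeats']}% of all repeats)")

truth = bundle.truth.target_genes | bundle.truth.target_repeats
tp = len(consensus & truth)
print(f"vs planted truth : precision {tp / len(consensus):.2f}, "
      f"recall {tp / len(truth):.2f}")
# The percentages mirror the genome-wide survey this emulates: the mark
# sits on ~4% of genes but half of all repetitive elements.
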