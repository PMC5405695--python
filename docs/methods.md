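# Methods

This note documents what the package computes, the parameters that
matter, what the synthetic study generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Scope and model

The pipeline operates downstream of read mapping and peak calling: its
inputs are a genome annotation (GFF3/BED), chromosome sizes and sequence
(FASTA), per-replicate coverage (bedGraph) for the H3K27me3 IP, the input
and an H3 control, per-replicate peak calls (BED), an expression table
(locus → FPKM) and a GO map (locus → terms). Internally all coordinates
are 0-based half-open; GFF3's 1-based closed convention is converted at
the I/O boundary, and abutting intervals do not overlap. Unknown
chromosomes are an error rather than a silent skip, because dropped
contigs would corrupt genome-coverage fractions.

### Peak annotation and consensus

The overlap fraction of a peak with a locus is the covered share of the
*locus* length, computed per peak (not per union of peaks over the
locus — multiple peaks on one locus are deduplicated afterwards, which is
why the duplicate-removal step exists at all). The 50 % threshold is
inclusive (≥). A peak overlapping several loci is assigned only its
best-covered locus; ties break deterministically by smaller locus start,
then lexicographic id. Strand is ignored: the intersection is positional.
Consensus requires a locus in ≥ `min_replicates` (default 2 of 3)
replicate target sets; it is antitone in `min_replicates` by
construction. Peak-to-feature distances are unsigned gap distances (0 for
any overlap), mirroring `bedtools closest`.

### De novo annotation cascade

Unannotated peaks are translated in six frames; ORFs are ATG-to-stop with
a 25-aa minimum (start-to-stop is the common ORF-finder convention; the
minimum suppresses spurious few-codon ORFs). ORFs reaching the sequence
end without a stop are kept open-ended. The longest ORF (ties: frame
order +1,+2,+3,−1,−2,−3, then smaller start) is searched against the
protein collection; failures fall through to a nucleotide search of the
raw peak DNA. Only the single top-scoring hit is considered, and it is
accepted only when alignment length strictly exceeds 50 % of the query
length (the query-length denominator is a documented choice; the
alternative — subject length — is not used) and the E-value is strictly
below 0.5.

The built-in backend is Smith–Waterman with affine gaps (BLOSUM62, open
11 / extend 1 for proteins; match +2 / mismatch −3, open 5 / extend 2 for
nucleotides) and Karlin–Altschul E-values with K = 0.041, λ = 0.267
(protein) and K = 0.41, λ = 0.625 (nucleotide). E-values are computed
against an **effective database size** (default 10⁸ residues, the scale
of a comprehensive reference collection) rather than the literal size of
the local records — the same convention as BLAST's `-dbsize` option. This
matters: against a toy database of a few thousand residues, an absolute
threshold of E < 0.5 would admit roughly a quarter of random-ORF queries,
because E-values are calibrated so that P(E < e) ≈ 1 − e^(−e) for random
sequences; thresholds chosen for a comprehensive-database search are only
meaningful at a comprehensive-database search space. Profile-HMM (Pfam)
search is out of scope; the protein stage subsumes its role in the
cascade. Complete-genome records can be excluded from the nucleotide
collection by flag.

### Profile matrices and clustering

Each region contributes 0.5 kb upstream flank + body + 0.5 kb downstream
flank in 50 bp bins; the body is linearly resampled (interpolation of bin
values at evenly spaced positions) to 10 bins regardless of true length,
flanks stay at native scale, and minus-strand rows are reversed so
columns always read 5′→3′. Values are the ratio
(IP + pseudocount)/(input + pseudocount) with pseudocount 1 — a plain
ratio, not a log-ratio, keeping values non-negative for heatmap-style
summaries; with strictly positive tracks and pseudocount 0 the matrix is
invariant to common rescaling of IP and input. Flanks running past a
chromosome edge are zero-padded and the row flagged; regions shorter than
one bin are resampled from their full extent and flagged. Replicates are
pooled by averaging their normalized matrices.

Clustering is standard k-means (k-means++ initialization, 10 restarts,
fixed seed) on raw profile values, k = 4 for genes and k = 3 for repeats
with no model selection — the cluster counts are part of the analysis
design, not fitted. Reported labels are sorted by descending mean body
enrichment (ties by descending downstream-flank mean), so "cluster 1" is
always the body-enriched cluster and membership sets are stable across
k-means seeds whenever the clusters are separated. Non-target rows stay
in the matrix; they form the last cluster.

### Expression, chromosome ends, GO

Expression comparisons use the classical equal-variance Student t-test
(Welch available via `equal_var=False`); multi-replicate FPKM columns are
averaged per locus before testing, and loci without FPKM are excluded
with a logged count. For degenerate zero-variance inputs the statistic is
defined as t = 0, p = 1 (identical groups) or ±∞, p = 0. Error bars are
standard errors over loci.

Chromosome-end analysis merges peaks whose gaps are ≤ 500 bp (one
nucleosome-scale bin) into domains — idempotently — and classifies an end
as enriched when a domain supported by ≥ `min_replicates` replicates lies
within 2 kb. The 2 kb default accepts genuinely terminal
telomere/subtelomere domains (telomeres are ≤ 700 bp here) while
rejecting domains 4–5 kb from an end; both the distance and the merge gap
are configurable, and the enriched count is monotone in both.

GO enrichment uses flat term sets (no DAG ancestor propagation, which
would change counts in ways not specifiable from per-term testing), a
one-sided Fisher exact test computed as the hypergeometric upper tail,
and Benjamini–Yekutieli step-up adjustment within each sub-ontology
separately (the sub-ontologies are reported separately, so each is its
own multiple-testing family). The minimum-entries filter — at least 5
*target* genes carrying the term, an interpretation documented here
because "entries" could also mean reference genes — is applied before
testing, so filtered terms never enter the family. Percentages are
rounded half-up (one decimal for coverage, integer for composition).

## The synthetic study generator

`simulate_study` produces a complete truth-annotated bundle at desk
scale: 20 chromosomes × 50 kb (1 Mb total — a scaled-down stand-in for a
16 Mb genome, keeping 25 genes per chromosome at the 1-gene-per-2-kb
density), telomeres drawn uniformly from 400–700 bp, 2 repeats per
chromosome, 3 IP replicates plus input and H3 tracks in 50 bp bins,
log-normal FPKM and a ~25-term GO vocabulary. Planted structure:

* **Marked loci.** 4 % of genes and 50 % of repeats; gene archetypes
  body/downstream/upstream in 0.4/0.3/0.3 proportions, repeat archetypes
  body and upstream+body in halves. Enrichment is a 4-fold coverage
  elevation over the archetype's span; flank archetypes additionally get
  a milder 2-fold elevation over the adjacent 70 % of the body, and their
  peaks span flank + that body portion so a jittered peak still covers
  more than half of its locus.
* **Chromosome ends.** 36 of 40 ends carry a terminal domain
  (1.2–1.9 kb, covering telomere + subtelomere); each remaining end gets
  a decoy domain whose distance from the end is drawn from 4–5 kb.
* **Hidden genes.** 10 real ORFs (120–160 aa) embedded in intergenic
  sequence, omitted from the annotation, covered by a peak in all
  replicates, and emitted to the protein reference. The generator
  guarantees each is the unique longest ORF in any jittered peak window
  (spurious longer ORFs in the random flanks are broken with a stop
  codon), keeping the longest-ORF rule unambiguous.
* **Peaks.** Planted spans with ±10 % boundary jitter per replicate. Each
  marked locus can be dropped from at most one replicate (per-replicate
  probability 0.1, capped so every target remains in ≥ 2 replicates and
  the 2-of-3 consensus is exercised without being destroyed). There is no
  empirical replicate noise model to copy here; dropout and jitter are
  assumptions, configurable.
* **Expression.** FPKM ~ LogNormal(μ = 2, σ = 0.6) with multiplicative
  repression: ×0.04 for body-archetype genes, ×0.25 for flank archetypes,
  ×0.15 for marked repeats; all repeats carry a class factor of 0.3 so
  repeats are less expressed than genes irrespective of the mark.
* **GO.** ~50 % of genes carry 1–3 background terms; the
  intein/protein-splicing term is forced onto every upstream-archetype
  (subtelomeric) gene and sprinkled on 1 % of the background, making it
  the one over-represented term among targets.

A single numpy Generator keyed by `seed` is consumed in a fixed order
(telomeres → end selection → layout → sequences → strands → signal →
peaks → expression → GO), so a seed reproduces the bundle bit-exactly,
including the emitted files.

**Layout and what passing tests do and do not show.** Marked loci, hidden
genes and decoy peaks are placed in clearance-padded slots (800 bp around
marked loci, 600 bp around unannotated signal) so that planted enrichment
never reaches a neighbouring gene's flank window, and
upstream-archetype genes are pinned to the outermost (subtelomeric) slot
of a chromosome with an enriched end. This makes archetype recovery
essentially exact and is a deliberate idealization: real gene-dense
genomes have no such clearance, neighbouring signal does bleed into flank
windows, and real cluster boundaries are correspondingly fuzzier. Tests
passing on this generator demonstrate that the pipeline's logic is
correct and its thresholds mutually consistent — not that clustering or
consensus calling would achieve these scores on real data. Other
simplifications: coverage is generated directly as binned signal (no
reads, no duplicates, no mappability structure), peak boundaries derive
from truth rather than a caller, and decoy/terminal regions are the only
unannotated signal.

## Problem sizes and defaults

The default study (1 Mb, 500 genes, 40 repeats, ~100 peaks per
replicate) was chosen so that a full simulate-analyze cycle takes well
under a second and the entire suite, including the 500-draw null
calibration of the t-test and the end-to-end recovery checks, completes
in a few seconds. The null calibration draws 200 + 200 loci per
iteration from the same log-normal, matching the scale at which the
expression comparison is used.

## Known limitations

* The built-in homology backend is exact Smith–Waterman, fine for
  kb-scale peaks against small references but not a substitute for BLAST
  on real databases; the outfmt-6 adapter exists for that.
* Karlin–Altschul parameters are fixed constants, not fitted to the
  scoring system per query (no composition-based adjustment).
* BY monotonicity under family shrinkage is asserted empirically in the
  tests on random families, not proved.
* The generator emits one FPKM per locus; replicate-level RNA noise is
  only supported through extra expression columns at the I/O layer.
* GFF3 support is deliberately minimal (flat features with `ID`/`Note`),
  matching the single-level annotations of compact genomes.
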