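# merochip

Genome-wide characterization of the repressive Polycomb mark **H3K27me3**
in a compact, gene-dense algal genome — the downstream half of a
ChIP-seq/RNA-seq survey, rebuilt as a tested, reusable Python library.

The package is aimed at chromatin biologists and bioinformaticians working
with small eukaryotic genomes (the model here is a ~16 Mb, 20-chromosome,
intron-poor red-algal genome with short 400–700 bp telomeres). It starts
where peak calling ends, and covers:

* **Peak → locus annotation and consensus calling.** A peak is matched to
  the locus whose length it covers best; with overlap fraction
  *f* = overlap_bp / locus_length, peaks with *f* ≥ 0.5 are
  *high-overlap* annotations, 0 < *f* < 0.5 *low-overlap*, and *f* = 0
  unannotated. Per replicate, duplicate calls on one locus are collapsed;
  a locus is a **consensus target** when called in ≥ 2 of 3 replicates.
* **De novo annotation of orphan peaks.** Six-frame ATG-to-stop ORF
  extraction, longest-ORF selection, Smith–Waterman protein search, then a
  nucleotide fallback — a hit is accepted only with alignment length
  > 50 % of the query and Karlin–Altschul E = K·m·n·e^(−λS) < 0.5 (both
  strict). An external BLAST run can replace the built-in backend via the
  tabular (outfmt 6) adapter.
* **Scale-regions profile clustering.** Per-gene rows of
  (IP + 1)/(input + 1) enrichment over 0.5 kb flanks and a body rescaled
  to 0.5 kb (50 bp bins, strand-aware), k-means clustered (k = 4 genes,
  k = 3 repeats) with clusters renamed by descending body enrichment, so
  cluster 1 is always the body-enriched (most repressed) cluster.
* **Expression integration.** Target vs non-target FPKM comparison per
  feature class with an equal-variance Student t-test (Welch behind a
  flag).
* **Chromosome-end enrichment.** Peaks merged into domains (gap ≤ 500 bp);
  an end is enriched when a ≥ 2-replicate domain lies within 2 kb.
* **GO enrichment.** One-sided Fisher exact tests per term (≥ 5 target
  entries), Benjamini–Yekutieli FDR within each sub-ontology.
* **A truth-annotated synthetic study generator** (`merochip.simulate`)
  that emulates the survey's data structure — 3 ChIP replicates with input
  and H3 controls, 4 % of genes and 50 % of repeats marked, terminal
  domains at 36 of 40 chromosome ends, hidden genes absent from the
  annotation, expression anti-correlated with the mark — so every stage is
  testable without downloads.

## Worked example

```bash
python examples/02_peak_annotation.py
```

```
IP1: {'unannotated': 60, 'high_overlap': 38}
IP2: {'unannotated': 60, 'high_overlap': 37}
IP3: {'unannotated': 60, 'high_overlap': 36}

consensus targets: 40
genes  : 20 (4% of all genes)
repeats: 20 (50% of all repeats)
vs planted truth : precision 1.00, recall 1.00
```

Each replicate annotates 36–38 peaks onto loci at high overlap (the
remaining peaks sit over terminal domains, hidden genes and intergenic
decoys); the 2-of-3 consensus recovers exactly the planted target set:
the mark covers 4 % of genes but half of all repetitive elements. The
other examples walk through simulation (`01`), profile clustering and
its expression ordering (`03`), chromosome-end classification (`04`) and
the expression/GO integration (`05`).

A thin CLI wraps the same library calls:

```bash
merochip simulate --seed 42 --out study/
merochip annotate --peaks study/peaks_IP1.bed --peaks study/peaks_IP2.bed \
    --peaks study/peaks_IP3.bed --annotation study/annotation.gff3 --out ann/
merochip ends --peaks study/peaks_IP1.bed --peaks study/peaks_IP2.bed \
    --peaks study/peaks_IP3.bed --chrom-sizes study/genome.sizes --out ends/
```

## Layout

```
src/merochip/      model, io, simulate, annotate, denovo, profiles,
                   expression, domains, go, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and end-to-end recovery)
docs/methods.md    model, parameters, numerical choices, limitations
```
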