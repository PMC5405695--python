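"""Truth-annotated synthetic H3K27me3 study generator.

Emulates the data structure of a ChIP-seq/RNA-seq survey of a compact,
gene-dense, intron-poor red-algal genome: 20 chromosomes with short
(400-700 bp) telomeres, ~1 gene per 2 kb, sparse repetitive elements,
three ChIP replicates with an input and an H3 control, H3K27me3
enrichment planted on 4% of genes, 50% of repeats and 36 of the 40
chromosome ends, expression anti-correlated with the mark, and a GO
vocabulary whose intein/protein-splicing term is over-represented among
marked subtelomeric genes. Every planted fact is recorded in
:class:`SyntheticTruth` so downstream stages can be scored against it.

Design notes
------------
* One ``numpy`` Generator keyed by ``params.seed`` is consumed in a fixed
  order (telomeres, end selection, per-chromosome layout, sequences,
  marking, coverage, peaks, expression, GO), so the same seed yields a
  bit-identical bundle.
* Coverage is generated directly as binned signal; no read simulation.
* Peak calls are the planted enrichment domains with +/-10% boundary
  jitter. Each marked locus may be dropped from at most one replicate
  (per-replicate probability 0.1), so the 2-of-3 consensus is exercised
  while every target stays detectable in at least two replicates.
* Flank-archetype peaks span the 500 bp flank plus 70% of the adjacent
  gene body, so a jittered peak still covers more than half of its locus.
* Hidden genes are real ORFs embedded in intergenic sequence, absent from
  the annotation but present in the protein reference; the generator
  guarantees each is the unique longest ORF within any jittered peak
  window, keeping the longest-ORF selection rule unambiguous.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .denovo import _translate, revcomp, six_frame_orfs
from .go import GOAnnotationMap
from .model import (
    CoverageTrack,
    Feature,
    GenomeModel,
    Interval,
    Peak,
    ValidationError,
)

TELOMERE_UNIT = "AATGGGGGG"
ENRICHED_GO_TERM = "GO:0016539"

_BP_TERMS = {
    "GO:0016539": "intein-mediated protein splicing",
    "GO:0006412": "translation",
    "GO:0006096": "glycolytic process",
    "GO:0006355": "regulation of transcription",
    "GO:0007165": "signal transduction",
    "GO:0006508": "proteolysis",
    "GO:0006810": "transport",
    "GO:0016310": "phosphorylation",
    "GO:0032502": "developmental process",
}
_MF_TERMS = {
    "GO:0003824": "catalytic activity",
    "GO:0005515": "protein binding",
    "GO:0016740": "transferase activity",
    "GO:0016787": "hydrolase activity",
    "GO:0005215": "transporter activity",
    "GO:0003677": "DNA binding",
    "GO:0000166": "nucleotide binding",
    "GO:0008233": "peptidase activity",
}
_CC_TERMS = {
    "GO:0005737": "cytoplasm",
    "GO:0005634": "nucleus",
    "GO:0016020": "membrane",
    "GO:0009507": "chloroplast",
    "GO:0005739": "mitochondrion",
    "GO:0005840": "ribosome",
}

TERM_META: Dict[str, Tuple[str, str]] = {}
for _terms, _sub in (
    (_BP_TERMS, "biological_process"),
    (_MF_TERMS, "molecular_function"),
    (_CC_TERMS, "cellular_component"),
):
    for _t, _n in _terms.items():
        TERM_META[_t] = (_n, _sub)


@dataclass
class SimulationParams:
    """Study conditions. Defaults mirror the surveyed genome and the
    fractions the analysis is meant to recover."""

    n_chromosomes: int = 20
    chrom_length_bp: int = 50_000
    gene_density_bp: int = 2_000  # one gene per this many bp
    repeat_count: int = 2  # repetitive elements per chromosome
    telomere_bp: Tuple[int, int] = (400, 700)
    fraction_genes_marked: float = 0.04
    fraction_repeats_marked: float = 0.50
    n_enriched_ends: int = 36
    n_hidden_genes: int = 10
    n_decoy_peaks: int = 10
    # layout
    end_margin_bp: int = 2_600  # first/last feature offset from the ends
    gene_length_bp: Tuple[int, int] = (650, 950)
    repeat_length_bp: Tuple[int, int] = (300, 600)
    intergenic_gap_bp: Tuple[int, int] = (250, 400)
    unannotated_clearance_bp: int = 600  # keeps gene flanks clear of planted
    # unannotated signal (hidden genes, decoy peaks, end-decoy domains)
    marked_clearance_bp: int = 800  # keeps neighbours' flanks clear of planted
    # enrichment, so unmarked profile rows are genuinely flat
    decoy_peak_bp: int = 250
    hidden_orf_aa: Tuple[int, int] = (120, 160)
    hidden_peak_flank_bp: int = 80
    terminal_domain_bp: Tuple[int, int] = (1_200, 1_900)
    decoy_end_offset_bp: Tuple[int, int] = (4_000, 5_000)
    decoy_end_domain_bp: int = 600
    plant_end_decoys: bool = True  # a near-terminal domain 4-5 kb from each
    # non-enriched end; off gives those chromosomes bare ends
    # signal
    bin_bp: int = 50
    enrichment_fold: float = 4.0
    flank_body_fold: float = 2.0  # body elevation of flank-archetype genes
    body_cover_frac: float = 0.7  # body fraction covered by flank-archetype peaks
    noise_sd: float = 0.1
    jitter_frac: float = 0.1
    replicate_dropout: float = 0.1
    n_replicates: int = 3
    # expression
    fpkm_log_mean: float = 2.0
    fpkm_log_sd: float = 0.6
    repeat_class_factor: float = 0.3  # repeats expressed lower than genes, mark or not
    repression_factors: Dict[str, float] = field(
        default_factory=lambda: {"body": 0.04, "downstream": 0.25, "upstream": 0.25}
    )
    repeat_repression_factor: float = 0.15
    archetype_props: Tuple[float, float, float] = (0.4, 0.3, 0.3)  # body, downstream, upstream
    # GO
    go_coverage: float = 0.5
    enriched_term_background: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_genes_marked", "fraction_repeats_marked", "go_coverage"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_enriched_ends > 2 * self.n_chromosomes:
            raise ValidationError("n_enriched_ends exceeds the number of chromosome ends")
        if self.n_hidden_genes > self.n_chromosomes or self.n_decoy_peaks > self.n_chromosomes:
            raise ValidationError("at most one hidden gene / decoy peak per chromosome")


@dataclass
class SyntheticTruth:
    target_genes: Set[str]
    target_repeats: Set[str]
    archetype_of: Dict[str, str]  # body | downstream | upstream | upstream_body | none
    enriched_ends: Set[Tuple[str, str]]  # (chrom, "5p"|"3p")
    hidden_genes: List[Feature]
    enriched_go_term: str


@dataclass
class StudyBundle:
    params: SimulationParams
    genome: GenomeModel
    sequences: Dict[str, str]
    features: List[Feature]  # the emitted annotation (hidden genes excluded)
    tracks: Dict[str, CoverageTrack]  # input, h3, IP1..IPn
    peaks: Dict[str, List[Peak]]  # replicate -> peaks
    fpkm: pd.Series
    go_map: GOAnnotationMap
    proteins: Dict[str, str]  # hidden-gene protein reference
    truth: SyntheticTruth

    @property
    def gene_features(self) -> List[Feature]:
        return [f for f in self.features if f.feature_class == "gene"]

    @property
    def repeat_features(self) -> List[Feature]:
        return [f for f in self.features if f.feature_class == "repeat"]


# ---------------------------------------------------------------------------
# layout


def _chrom_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def _layout_chromosome(
    rng: np.random.Generator,
    params: SimulationParams,
    chrom: str,
    marked_gene_slots: Sequence[Tuple[str, Optional[str]]],
    marked_repeat_slots: Sequence[str],
    want_hidden: bool,
    want_decoy: bool,
    reserved: List[Tuple[int, int]],
) -> List[Tuple[str, int, int, Optional[str]]]:
    """Place features left to right with random intergenic gaps.

    ``marked_gene_slots`` are (archetype, position) pairs; position
    ``first``/``last`` pins a marked gene to the outermost (subtelomeric)
    slot, ``None`` leaves it anywhere. Marked features and unannotated
    signal (hidden genes, decoy peaks) carry clearance padding so the
    planted enrichment never reaches a neighbour's 500 bp flank window.

    Returns (kind, start, end, archetype) tuples; kind in
    gene/marked_gene/repeat/marked_repeat/hidden/decoy. Raises on
    infeasible packing (density too high for the chromosome).
    """
    n_genes = params.chrom_length_bp // params.gene_density_bp
    n_plain_genes = n_genes - len(marked_gene_slots)
    n_plain_repeats = params.repeat_count - len(marked_repeat_slots)
    if n_plain_genes < 0 or n_plain_repeats < 0:
        raise ValidationError(
            f"infeasible marking on {chrom}: more marked loci than features"
        )
    interior: List[Tuple[str, Optional[str]]] = [("gene", None)] * n_plain_genes
    interior += [("repeat", None)] * n_plain_repeats
    interior += [("marked_gene", arch) for arch, pos in marked_gene_slots if pos is None]
    interior += [("marked_repeat", arch) for arch in marked_repeat_slots]
    if want_hidden:
        interior.append(("hidden", None))
    if want_decoy:
        interior.append(("decoy", None))
    interior = [interior[i] for i in rng.permutation(len(interior))]
    first = [("marked_gene", arch) for arch, pos in marked_gene_slots if pos == "first"]
    last = [("marked_gene", arch) for arch, pos in marked_gene_slots if pos == "last"]
    kinds = first + interior + last

    out: List[Tuple[str, int, int, Optional[str]]] = []
    cursor = params.end_margin_bp
    limit = params.chrom_length_bp - params.end_margin_bp
    clearance = params.unannotated_clearance_bp
    for kind, arch in kinds:
        cursor += int(rng.integers(params.intergenic_gap_bp[0], params.intergenic_gap_bp[1] + 1))
        if kind in ("gene", "marked_gene"):
            length = int(rng.integers(params.gene_length_bp[0], params.gene_length_bp[1] + 1))
        elif kind in ("repeat", "marked_repeat"):
            length = int(rng.integers(params.repeat_length_bp[0], params.repeat_length_bp[1] + 1))
        elif kind == "hidden":
            aa = int(rng.integers(params.hidden_orf_aa[0], params.hidden_orf_aa[1] + 1))
            length = 3 * aa + 3  # ATG..codons..stop
        else:  # decoy
            length = params.decoy_peak_bp
        if kind in ("hidden", "decoy"):
            pad = clearance
        elif kind in ("marked_gene", "marked_repeat"):
            pad = params.marked_clearance_bp
        else:
            pad = 0
        cursor += pad
        for r_start, r_end in reserved:
            if cursor < r_end + clearance and cursor + length > r_start - clearance:
                cursor = r_end + clearance
        if cursor + length > limit:
            raise ValidationError(
                f"infeasible packing on {chrom}: feature density too high for "
                f"{params.chrom_length_bp} bp"
            )
        out.append((kind, cursor, cursor + length, arch))
        cursor += length + pad
    return out


# ---------------------------------------------------------------------------
# sequence


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SAFE_CODONS = [
    c
    for c in ("".join((a, b, d)) for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA")
]


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASE_BYTES[rng.integers(0, 4, size=length)].tobytes())


def _embed_telomeres(seq: bytearray, t5: int, t3: int) -> None:
    unit = TELOMERE_UNIT
    left = (unit * (t5 // len(unit) + 1))[:t5]
    right = revcomp((unit * (t3 // len(unit) + 1))[:t3])
    seq[:t5] = left.encode()
    seq[len(seq) - t3 :] = right.encode()


def _embed_orf(rng: np.random.Generator, seq: bytearray, start: int, end: int) -> str:
    """Write an ATG..stop ORF into [start, end) and return its peptide."""
    n_codons = (end - start) // 3 - 1  # coding codons incl. the ATG
    codons = ["ATG"] + [
        _SAFE_CODONS[int(i)] for i in rng.integers(0, len(_SAFE_CODONS), size=n_codons - 1)
    ]
    dna = "".join(codons) + "TAA"
    seq[start:end] = dna.encode()
    return _translate("".join(codons))


def _enforce_unique_longest(
    seq: bytearray, win_start: int, win_end: int, orf_start: int, orf_end: int, orf_aa: int
) -> None:
    """Break any ORF in the window at least as long as the planted one."""
    for _ in range(30):
        window = seq[win_start:win_end].decode()
        offenders = [
            o
            for o in six_frame_orfs(window, min_aa=orf_aa)
            if not (win_start + o.nt_start == orf_start and win_start + o.nt_end == orf_end)
        ]
        if not offenders:
            return
        o = offenders[0]
        abs_start, abs_end = win_start + o.nt_start, win_start + o.nt_end
        n_codons = (abs_end - abs_start) // 3
        for k in range(n_codons):
            if o.frame > 0:
                c0 = abs_start + 3 * k
            else:
                c0 = abs_end - 3 * (k + 1)
            if c0 >= orf_end or c0 + 3 <= orf_start:  # never touch the planted ORF
                seq[c0 : c0 + 3] = b"TAA" if o.frame > 0 else b"TTA"  # rev-strand stop
                break
        else:  # pragma: no cover - offender nested inside the planted ORF
            raise ValidationError("cannot break spurious ORF without touching the planted one")
    else:  # pragma: no cover
        raise ValidationError("failed to make the planted ORF unique-longest")


# ---------------------------------------------------------------------------
# the study


def _jitter(
    rng: np.random.Generator, start: int, end: int, frac: float, chrom_len: int
) -> Tuple[int, int]:
    w = end - start
    s = start + int(round(rng.uniform(-frac, frac) * w))
    e = end + int(round(rng.uniform(-frac, frac) * w))
    s = max(0, s)
    e = min(chrom_len, max(e, s + 1))
    return s, e


def _peak_region(feat: Feature, archetype: str, params: SimulationParams) -> Tuple[int, int]:
    """The planted enrichment/peak span for a marked feature."""
    iv = feat.interval
    L = iv.width
    fwd = iv.strand != "-"
    cover = int(round(params.body_cover_frac * L))
    if archetype == "body":
        return iv.start, iv.end
    if archetype == "upstream_body":
        if fwd:
            return iv.start - 500, iv.end
        return iv.start, iv.end + 500
    if archetype == "downstream":
        if fwd:
            return iv.end - cover, iv.end + 500
        return iv.start - 500, iv.start + cover
    if archetype == "upstream":
        if fwd:
            return iv.start - 500, iv.start + cover
        return iv.end - cover, iv.end + 500
    raise ValidationError(f"unknown archetype {archetype!r}")


def simulate_study(params: Optional[SimulationParams] = None) -> StudyBundle:
    """Generate the complete synthetic study for the given parameters."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    chrom_names = [_chrom_name(i) for i in range(params.n_chromosomes)]
    chrom_len = params.chrom_length_bp

    # 1. telomeres
    telomeres = {
        c: (
            int(rng.integers(params.telomere_bp[0], params.telomere_bp[1] + 1)),
            int(rng.integers(params.telomere_bp[0], params.telomere_bp[1] + 1)),
        )
        for c in chrom_names
    }
    genome = GenomeModel([(c, chrom_len) for c in chrom_names], telomeres)

    # 2. which chromosome ends carry a terminal domain
    all_ends = [(c, e) for c in chrom_names for e in ("5p", "3p")]
    n_plain = 2 * params.n_chromosomes - params.n_enriched_ends
    plain_idx = sorted(rng.choice(len(all_ends), size=n_plain, replace=False))
    plain_ends = [all_ends[i] for i in plain_idx]
    enriched_ends = {e for e in all_ends if e not in set(plain_ends)}

    # 3. per-chromosome layout (decoy end-domains are reserved first)
    end_decoys: Dict[Tuple[str, str], Tuple[int, int]] = {}
    for c, e in plain_ends if params.plant_end_decoys else []:
        off = int(rng.integers(params.decoy_end_offset_bp[0], params.decoy_end_offset_bp[1] + 1))
        if e == "5p":
            end_decoys[(c, e)] = (off, off + params.decoy_end_domain_bp)
        else:
            end_decoys[(c, e)] = (chrom_len - off - params.decoy_end_domain_bp, chrom_len - off)

    # 3a. allocate marked loci to chromosomes before layout: marked slots
    # carry clearance padding, and upstream-archetype genes are pinned to a
    # subtelomeric slot at an enriched end
    n_genes_per_chrom = chrom_len // params.gene_density_bp
    total_genes = n_genes_per_chrom * params.n_chromosomes
    n_marked = int(round(params.fraction_genes_marked * total_genes))
    p_body, p_down, p_up = params.archetype_props
    n_up = int(round(p_up * n_marked))
    n_down = int(round(p_down * n_marked))
    n_body = n_marked - n_up - n_down
    end_slots = sorted(enriched_ends)
    if n_up > len(end_slots):
        raise ValidationError("more upstream-archetype genes than enriched ends")
    up_pick = sorted(rng.choice(len(end_slots), size=n_up, replace=False))
    marked_gene_slots: Dict[str, List[Tuple[str, Optional[str]]]] = {
        c: [] for c in chrom_names
    }
    for i in up_pick:
        c, e = end_slots[i]
        marked_gene_slots[c].append(("upstream", "first" if e == "5p" else "last"))
    pool: List[str] = []
    while len(pool) < n_down + n_body:  # spread marks evenly across chromosomes
        pool.extend(chrom_names)
    pool = [pool[i] for i in rng.permutation(len(pool))][: n_down + n_body]
    archs = ["downstream"] * n_down + ["body"] * n_body
    archs = [archs[i] for i in rng.permutation(len(archs))]
    for c, a in zip(pool, archs):
        marked_gene_slots[c].append((a, None))

    total_repeats = params.repeat_count * params.n_chromosomes
    n_marked_rep = int(round(params.fraction_repeats_marked * total_repeats))
    rep_pool = [c for c in chrom_names for _ in range(params.repeat_count)]
    rep_pool = [rep_pool[i] for i in rng.permutation(len(rep_pool))][:n_marked_rep]
    rep_archs = ["body"] * (n_marked_rep // 2)
    rep_archs += ["upstream_body"] * (n_marked_rep - len(rep_archs))
    rep_archs = [rep_archs[i] for i in rng.permutation(len(rep_archs))]
    marked_repeat_slots: Dict[str, List[str]] = {c: [] for c in chrom_names}
    for c, a in zip(rep_pool, rep_archs):
        marked_repeat_slots[c].append(a)

    hidden_chroms = set(chrom_names[: params.n_hidden_genes])
    decoy_chroms = set(chrom_names[params.n_chromosomes - params.n_decoy_peaks :])
    layout: Dict[str, List[Tuple[str, int, int, Optional[str]]]] = {}
    for c in chrom_names:
        reserved = [span for (cc, _e), span in end_decoys.items() if cc == c]
        layout[c] = _layout_chromosome(
            rng, params, c, marked_gene_slots[c], marked_repeat_slots[c],
            c in hidden_chroms, c in decoy_chroms, sorted(reserved),
        )

    features: List[Feature] = []
    hidden_specs: List[Tuple[str, int, int]] = []  # chrom, start, end
    decoy_regions: List[Tuple[str, int, int]] = []
    archetype_of: Dict[str, str] = {}
    up_genes: List[str] = []
    down_genes: List[str] = []
    body_genes: List[str] = []
    rep_body: List[str] = []
    rep_up_body: List[str] = []
    gene_i = repeat_i = hidden_i = 0
    for c in chrom_names:
        for kind, start, end, arch in layout[c]:
            strand = "+" if rng.random() < 0.5 else "-"
            if kind in ("gene", "marked_gene"):
                gene_i += 1
                locus = f"CMS{gene_i:04d}G"
                features.append(Feature(Interval(c, start, end, strand), locus, "gene"))
                archetype_of[locus] = arch or "none"
                if arch == "upstream":
                    up_genes.append(locus)
                elif arch == "downstream":
                    down_genes.append(locus)
                elif arch == "body":
                    body_genes.append(locus)
            elif kind in ("repeat", "marked_repeat"):
                repeat_i += 1
                locus = f"CMS{repeat_i:03d}R"
                features.append(Feature(Interval(c, start, end, strand), locus, "repeat"))
                archetype_of[locus] = arch or "none"
                if arch == "body":
                    rep_body.append(locus)
                elif arch == "upstream_body":
                    rep_up_body.append(locus)
            elif kind == "hidden":
                hidden_specs.append((c, start, end))
            else:
                decoy_regions.append((c, start, end))

    # 4. sequences (hidden ORFs embedded on the forward strand)
    sequences_list: Dict[str, bytearray] = {}
    for c in chrom_names:
        seq = _random_sequence(rng, chrom_len)
        t5, t3 = telomeres[c]
        _embed_telomeres(seq, t5, t3)
        sequences_list[c] = seq

    proteins: Dict[str, str] = {}
    hidden_features: List[Feature] = []
    for c, start, end in hidden_specs:
        hidden_i += 1
        locus = f"CMS{hidden_i:02d}H"
        peptide = _embed_orf(rng, sequences_list[c], start, end)
        flank = params.hidden_peak_flank_bp
        _enforce_unique_longest(
            sequences_list[c], max(0, start - 2 * flank), min(chrom_len, end + 2 * flank),
            start, end, len(peptide),
        )
        proteins[locus] = peptide
        hidden_features.append(Feature(Interval(c, start, end, "+"), locus, "gene"))
    sequences = {c: s.decode() for c, s in sequences_list.items()}

    # 5. truth assembly (marking was decided at layout time)
    genes = [f for f in features if f.feature_class == "gene"]
    truth = SyntheticTruth(
        target_genes=set(up_genes) | set(down_genes) | set(body_genes),
        target_repeats=set(rep_body) | set(rep_up_body),
        archetype_of=archetype_of,
        enriched_ends=enriched_ends,
        hidden_genes=hidden_features,
        enriched_go_term=ENRICHED_GO_TERM,
    )

    # 6. planted enrichment regions
    by_id = {f.locus_id: f for f in features}
    planted: List[Tuple[str, int, int, str, Optional[str]]] = []  # chrom, s, e, kind, locus
    for locus in sorted(truth.target_genes | truth.target_repeats):
        feat = by_id[locus]
        s, e = _peak_region(feat, archetype_of[locus], params)
        planted.append((feat.interval.chrom, s, e, "target", locus))
    terminal_spans: Dict[Tuple[str, str], Tuple[int, int]] = {}
    for c, e in sorted(enriched_ends):
        L = int(rng.integers(params.terminal_domain_bp[0], params.terminal_domain_bp[1] + 1))
        span = (0, L) if e == "5p" else (chrom_len - L, chrom_len)
        terminal_spans[(c, e)] = span
        planted.append((c, span[0], span[1], "terminal", None))
    for (c, e), span in sorted(end_decoys.items()):
        planted.append((c, span[0], span[1], "end_decoy", None))
    for h in hidden_features:
        iv = h.interval
        flank = params.hidden_peak_flank_bp
        planted.append((iv.chrom, iv.start - flank, iv.end + flank, "hidden", h.locus_id))
    for c, s, e in decoy_regions:
        planted.append((c, s, e, "decoy", None))

    # 7. coverage tracks (enrichment shared by replicates; noise per track)
    n_bins = -(-chrom_len // params.bin_bp)
    enrich: Dict[str, np.ndarray] = {c: np.ones(n_bins) for c in chrom_names}

    def _elevate(c: str, s: int, e: int, fold: float) -> None:
        b0, b1 = max(0, s) // params.bin_bp, -(-min(e, chrom_len) // params.bin_bp)
        enrich[c][b0:b1] = np.maximum(enrich[c][b0:b1], fold)

    for c, s, e, kind, locus in planted:
        _elevate(c, s, e, params.enrichment_fold)
    # flank-archetype gene bodies get a milder elevation over the covered part
    for locus in sorted(truth.target_genes):
        if archetype_of[locus] in ("downstream", "upstream"):
            feat = by_id[locus]
            s, e = _peak_region(feat, archetype_of[locus], params)
            iv = feat.interval
            _elevate(iv.chrom, max(s, iv.start), min(e, iv.end), params.flank_body_fold)

    def _noisy(base: np.ndarray) -> np.ndarray:
        return np.clip(base + rng.normal(0.0, params.noise_sd, size=base.shape), 0.05, None)

    tracks: Dict[str, CoverageTrack] = {}
    tracks["input"] = CoverageTrack(
        params.bin_bp, {c: _noisy(np.ones(n_bins)) for c in chrom_names}
    )
    tracks["h3"] = CoverageTrack(
        params.bin_bp, {c: _noisy(np.ones(n_bins)) for c in chrom_names}
    )
    for r in range(1, params.n_replicates + 1):
        tracks[f"IP{r}"] = CoverageTrack(
            params.bin_bp, {c: _noisy(enrich[c].copy()) for c in chrom_names}
        )

    # 8. peaks: jittered planted regions; targets dropped from <=1 replicate
    rep_names = [f"IP{r}" for r in range(1, params.n_replicates + 1)]
    peaks: Dict[str, List[Peak]] = {r: [] for r in rep_names}
    for c, s, e, kind, locus in planted:
        if kind == "target":
            drops = [r for r in rep_names if rng.random() < params.replicate_dropout]
            drops = drops[:1]  # keep every target in at least two replicates
        else:
            drops = []
        for r in rep_names:
            if r in drops:
                continue
            js, je = _jitter(rng, s, e, params.jitter_frac, chrom_len)
            peaks[r].append(Peak(Interval(c, js, je), r, score=float(params.enrichment_fold)))
    for r in rep_names:
        peaks[r].sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))

    # 9. expression
    fpkm_values: Dict[str, float] = {}
    for f in sorted(features, key=lambda f: f.locus_id):
        base = float(rng.lognormal(params.fpkm_log_mean, params.fpkm_log_sd))
        if f.feature_class == "repeat":
            base *= params.repeat_class_factor
            if f.locus_id in truth.target_repeats:
                base *= params.repeat_repression_factor
        else:
            arch = archetype_of[f.locus_id]
            if arch != "none":
                base *= params.repression_factors[arch]
        fpkm_values[f.locus_id] = base
    fpkm = pd.Series(fpkm_values, name="fpkm")

    # 10. GO annotation (genes only)
    go_map = make_go_map(
        rng,
        sorted(f.locus_id for f in genes),
        enriched_ids=set(up_genes),
        coverage=params.go_coverage,
        enriched_term_background=params.enriched_term_background,
    )

    return StudyBundle(
        params=params,
        genome=genome,
        sequences=sequences,
        features=features,
        tracks=tracks,
        peaks=peaks,
        fpkm=fpkm,
        go_map=go_map,
        proteins=proteins,
        truth=truth,
    )


def make_go_map(
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    enriched_ids: Set[str] = frozenset(),
    coverage: float = 0.5,
    enriched_term_background: float = 0.01,
) -> GOAnnotationMap:
    """Assign GO terms: background terms at the given coverage, plus the
    protein-splicing term forced onto ``enriched_ids`` (and sprinkled on a
    small background fraction). With ``enriched_ids`` empty the assignment
    is independent of any target status — a null vocabulary."""
    background = sorted(set(TERM_META) - {ENRICHED_GO_TERM})
    gene_terms: Dict[str, Set[str]] = {}
    for locus in gene_ids:
        terms: Set[str] = set()
        if rng.random() < coverage:
            k = int(rng.integers(1, 4))
            terms.update(rng.choice(background, size=k, replace=False).tolist())
        if rng.random() < enriched_term_background:
            terms.add(ENRICHED_GO_TERM)
        if locus in enriched_ids:
            terms.add(ENRICHED_GO_TERM)
        if terms:
            gene_terms[locus] = terms
    return GOAnnotationMap(gene_terms, dict(TERM_META))


def draw_fpkm(
    rng: np.random.Generator, n: int, log_mean: float = 2.0, log_sd: float = 0.6,
    factor: float = 1.0,
) -> np.ndarray:
    """Log-normal FPKM draws with a multiplicative repression factor."""
    return rng.lognormal(log_mean, log_sd, size=n) * factor


# ---------------------------------------------------------------------------
# emission


def write_study(bundle: StudyBundle, out_dir: str) -> dict:
    """Write the bundle as flat files; returns a manifest of files and
    record counts. Re-running with the same seed gives byte-identical
    output."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: Dict[str, dict] = {}

    def _emit(name: str, n_records: int) -> str:
        path = os.path.join(out_dir, name)
        manifest[name] = {"records": n_records}
        return path

    mio.write_annotation(bundle.features, _emit("annotation.gff3", len(bundle.features)))
    mio.write_chrom_sizes(bundle.genome, _emit("genome.sizes", len(bundle.genome.chromosomes)))
    mio.write_fasta(bundle.sequences, _emit("genome.fasta", len(bundle.sequences)))
    mio.write_fasta(bundle.proteins, _emit("proteins.fasta", len(bundle.proteins)))
    for name, track in bundle.tracks.items():
        n = sum(len(v) for v in track.data.values())
        mio.write_bedgraph(track, bundle.genome, _emit(f"{name}.bedgraph", n))
    for rep, ps in bundle.peaks.items():
        mio.write_peaks(ps, _emit(f"peaks_{rep}.bed", len(ps)))
    mio.write_expression(bundle.fpkm, _emit("expression.tsv", len(bundle.fpkm)))
    mio.write_go_table(bundle.go_map, _emit("go_map.tsv", len(bundle.go_map.gene_terms)))

    truth = bundle.truth
    truth_json = {
        "target_genes": sorted(truth.target_genes),
        "target_repeats": sorted(truth.target_repeats),
        "archetype_of": dict(sorted(truth.archetype_of.items())),
        "enriched_ends": sorted([c, e] for c, e in truth.enriched_ends),
        "hidden_genes": [
            {
                "locus_id": h.locus_id,
                "chrom": h.interval.chrom,
                "start": h.interval.start,
                "end": h.interval.end,
                "strand": h.interval.strand,
            }
            for h in truth.hidden_genes
        ],
        "enriched_go_term": truth.enriched_go_term,
    }
    with open(_emit("truth.json", len(truth_json)), "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(dict(sorted(manifest.items())), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
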