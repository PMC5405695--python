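"""De novo annotation of peaks with no reference locus.

The cascade mirrors a protein-first homology search: the peak sequence is
translated in all six frames, the longest ATG-to-stop ORF is searched
against a protein collection, and peaks failing the protein stage fall back
to a nucleotide search of the raw peak DNA. A single top hit is accepted
only when the alignment covers strictly more than ``aln_len_min`` of the
query length AND the E-value is strictly below ``evalue_max`` (the
thresholds ">50% alignment length, <0.5 E-value" are strict inequalities).

The built-in backend is Smith-Waterman local alignment (BLOSUM62 for
proteins) with Karlin-Altschul E-values. E-values are computed against a
configurable *effective* database size (default 1e8 residues) so that
significance reflects a search of a comprehensive sequence collection —
the same convention as BLAST's ``-dbsize`` option — rather than the
handful of records supplied locally. An external BLAST run can be attached
through the tabular (outfmt 6) adapter instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .model import Peak, PipelineConfig, ValidationError

logger = logging.getLogger(__name__)

FRAMES = (1, 2, 3, -1, -2, -3)
_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Karlin-Altschul parameters for the two built-in scoring systems
PROTEIN_K, PROTEIN_LAMBDA = 0.041, 0.267  # BLOSUM62, gap open 11 / extend 1
NUCL_K, NUCL_LAMBDA = 0.41, 0.625  # match 2 / mismatch -3, gap open 5 / extend 2


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def _translate(codons: str) -> str:
    return "".join(
        _CODON_TABLE.get(codons[i : i + 3], "X") for i in range(0, len(codons) - 2, 3)
    )


@dataclass(frozen=True)
class Orf:
    """An ATG-to-stop open reading frame.

    ``nt_start``/``nt_end`` are 0-based half-open on the *forward* strand
    and include the terminating stop codon when one is present (so the
    peptide then has one residue fewer than the span has codons); ORFs that
    run off the sequence end are open-ended and span coding codons only.
    """

    frame: int
    nt_start: int
    nt_end: int
    peptide: str

    def __post_init__(self) -> None:
        if (self.nt_end - self.nt_start) % 3:
            raise ValidationError("ORF length must be a multiple of 3")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    aln_len: int
    query_len: int


def six_frame_orfs(dna: str, min_aa: int = 25) -> List[Orf]:
    """All ATG-to-stop ORFs of at least ``min_aa`` residues, in six frames.

    ORFs running off the end of the sequence without a stop are kept
    open-ended. Codons containing N translate to X. An empty sequence gives
    an empty list.
    """
    dna = dna.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise ValidationError(f"invalid nucleotides {sorted(bad)}")
    n = len(dna)
    orfs: List[Orf] = []
    for frame in FRAMES:
        seq = dna if frame > 0 else revcomp(dna)
        offset = abs(frame) - 1
        i = offset
        while i + 3 <= n:
            if seq[i : i + 3] == "ATG":
                j = i
                while j + 3 <= n and seq[j : j + 3] not in _STOPS:
                    j += 3
                peptide = _translate(seq[i:j])
                span_end = j + 3 if j + 3 <= n else j  # include the stop codon
                if len(peptide) >= min_aa:
                    if frame > 0:
                        nt_start, nt_end = i, span_end
                    else:  # mirror back to forward-strand coordinates
                        nt_start, nt_end = n - span_end, n - i
                    orfs.append(Orf(frame, nt_start, nt_end, peptide))
                i = j + 3  # next ATG after the stop, same frame
            else:
                i += 3
    return orfs


def longest_orf(orfs: Sequence[Orf]) -> Orf:
    """The maximal-length ORF; ties break by frame order +1,+2,+3,-1,-2,-3,
    then by smaller forward-strand start."""
    if not orfs:
        raise ValidationError("no ORFs to choose from")
    return min(
        orfs, key=lambda o: (-len(o.peptide), FRAMES.index(o.frame), o.nt_start)
    )


def _aligner(protein: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if protein:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    return aligner


def local_align(
    query: str,
    subject: str,
    protein: bool = True,
) -> Tuple[float, int]:
    """Optimal Smith-Waterman local alignment score and length.

    Affine gaps (protein: BLOSUM62, open 11 / extend 1; nucleotide:
    match +2 / mismatch -3, open 5 / extend 2). Returns ``(score,
    aln_len)`` where ``aln_len`` counts aligned columns including gaps.
    """
    if not query or not subject:
        raise ValidationError("empty sequence")
    aligner = _aligner(protein)
    try:
        alignments = aligner.align(query, subject)
        score = float(alignments.score)
        aln_len = int(alignments[0].length) if score > 0 else 0
    except (ValueError, KeyError) as exc:
        raise ValidationError(f"alignment failed: {exc}") from None
    return score, aln_len


def evalue(score: float, m: int, n: float, K: float, lam: float) -> float:
    """Karlin-Altschul expectation: E = K * m * n * exp(-lambda * score)."""
    if K <= 0 or lam <= 0:
        raise ValidationError("K and lambda must be positive")
    return K * m * n * math.exp(-lam * score)


class BuiltinSearchBackend:
    """Smith-Waterman search of a query against an in-memory collection.

    Returns hits sorted by descending score (ties by subject id), with
    E-values computed against ``max(effective_db_residues, actual db
    residues)``.
    """

    def __init__(self, protein: bool, effective_db_residues: float = 1e8) -> None:
        self.protein = protein
        self.effective_db_residues = effective_db_residues
        self.K, self.lam = (PROTEIN_K, PROTEIN_LAMBDA) if protein else (NUCL_K, NUCL_LAMBDA)

    def search(self, query_id: str, query: str, db: Mapping[str, str]) -> List[HomologyHit]:
        actual = sum(len(s) for s in db.values())
        n_eff = max(self.effective_db_residues, float(actual))
        hits = []
        for subject_id in sorted(db):
            score, aln_len = local_align(query, db[subject_id], protein=self.protein)
            if score <= 0:
                continue
            hits.append(
                HomologyHit(
                    query_id=query_id,
                    subject_id=subject_id,
                    score=score,
                    evalue=evalue(score, len(query), n_eff, self.K, self.lam),
                    aln_len=aln_len,
                    query_len=len(query),
                )
            )
        hits.sort(key=lambda h: (-h.score, h.subject_id))
        return hits


def hits_from_blast_tab(path: str, query_lengths: Mapping[str, int]) -> List[HomologyHit]:
    """Adapter for an external BLAST run: parse tabular (outfmt 6) columns
    qseqid, sseqid, length, evalue, bitscore into the HomologyHit contract."""
    hits: List[HomologyHit] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            q, s, length, ev, bits = line.split("\t")[:5]
            hits.append(
                HomologyHit(
                    query_id=q,
                    subject_id=s,
                    score=float(bits),
                    evalue=float(ev),
                    aln_len=int(length),
                    query_len=query_lengths[q],
                )
            )
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def _passes(hit: HomologyHit, cfg: PipelineConfig) -> bool:
    # both thresholds strict: >50% of query length, <0.5 E-value
    return hit.aln_len > cfg.aln_len_min * hit.query_len and hit.evalue < cfg.evalue_max


@dataclass
class DeNovoCall:
    peak: Peak
    status: str  # de_novo_protein | de_novo_nucleotide | still_unknown
    hit: Optional[HomologyHit]


def annotate_unknown_peaks(
    unknown: Sequence[Peak],
    genome_seq: Mapping[str, str],
    protein_db: Mapping[str, str],
    nucl_db: Mapping[str, str],
    cfg: Optional[PipelineConfig] = None,
    nucl_db_complete_genomes: Iterable[str] = (),
) -> List[DeNovoCall]:
    """Run the protein-first, nucleotide-fallback annotation cascade.

    For each peak: extract its genomic sequence, take the longest six-frame
    ORF and search the protein collection; only the single top hit is
    considered, and it must pass both strict thresholds. Peaks without an
    ORF (logged) or failing the protein stage are searched as raw DNA
    against the nucleotide collection, from which records flagged as
    complete genomes are excluded. Everything else is still_unknown.
    """
    cfg = cfg or PipelineConfig()
    protein_backend = BuiltinSearchBackend(True, cfg.effective_db_residues)
    nucl_backend = BuiltinSearchBackend(False, cfg.effective_db_residues)
    excluded = set(nucl_db_complete_genomes)
    nucl_records = {k: v for k, v in nucl_db.items() if k not in excluded}

    calls: List[DeNovoCall] = []
    for idx, peak in enumerate(unknown):
        iv = peak.interval
        seq = genome_seq[iv.chrom][iv.start : iv.end]
        peak_id = f"{iv.chrom}:{iv.start}-{iv.end}"
        orfs = six_frame_orfs(seq, cfg.min_orf_aa)
        hit: Optional[HomologyHit] = None
        if orfs and protein_db:
            query = longest_orf(orfs).peptide
            top = protein_backend.search(peak_id, query, protein_db)
            if top and _passes(top[0], cfg):
                calls.append(DeNovoCall(peak, "de_novo_protein", top[0]))
                continue
        elif not orfs:
            logger.info("no ORF >= %d aa in peak %s; nucleotide stage", cfg.min_orf_aa, peak_id)
        if nucl_records:
            top = nucl_backend.search(peak_id, seq, nucl_records)
            if top and _passes(top[0], cfg):
                calls.append(DeNovoCall(peak, "de_novo_nucleotide", top[0]))
                continue
        calls.append(DeNovoCall(peak, "still_unknown", None))
    return calls
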