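"""Six-frame ORF extraction, local alignment, E-values and the annotation
cascade for orphan peaks."""

import math

import numpy as np
import pytest

from _oracles import sw_affine_oracle
from merochip.denovo import (
    BuiltinSearchBackend,
    HomologyHit,
    Orf,
    _passes,
    annotate_unknown_peaks,
    evalue,
    hits_from_blast_tab,
    local_align,
    longest_orf,
    revcomp,
    six_frame_orfs,
)
from merochip.model import Interval, Peak, PipelineConfig, ValidationError

AA = "ACDEFGHIKLMNPQRSTVWY"


def test_minimal_orf():
    (orf,) = six_frame_orfs("ATGAAATAA", min_aa=1)
    assert orf.frame == 1
    assert orf.peptide == "MK"
    assert (orf.nt_start, orf.nt_end) == (0, 9)  # stop codon included


def test_no_start_codon_means_no_orf():
    assert six_frame_orfs("CCCCCCCCCCCC", min_aa=1) == []
    assert six_frame_orfs("", min_aa=1) == []


def test_six_frame_revcomp_symmetry():
    rng = np.random.default_rng(9)
    for _ in range(20):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=300)])
        n = len(seq)
        fwd = six_frame_orfs(seq, min_aa=5)
        rev = six_frame_orfs(revcomp(seq), min_aa=5)
        # frames sign-flip and coordinates mirror
        mirrored = {(-o.frame, n - o.nt_end, n - o.nt_start, o.peptide) for o in fwd}
        assert mirrored == {(o.frame, o.nt_start, o.nt_end, o.peptide) for o in rev}


def test_longest_orf_tie_breaks():
    a = Orf(1, 0, 33, "M" + "A" * 9)
    b = Orf(-1, 60, 138, "M" + "A" * 24)
    c = Orf(2, 1, 79, "M" + "A" * 24)
    assert longest_orf([a, b, c]) is c  # + frame preferred at equal length
    assert longest_orf([a]) is a
    d = Orf(1, 30, 108, "M" + "A" * 24)
    e = Orf(1, 0, 78, "M" + "A" * 24)
    assert longest_orf([d, e]) is e  # smaller start at equal length and frame
    with pytest.raises(ValidationError):
        longest_orf([])


def test_local_align_identity_score():
    score, aln_len = local_align("MKV", "MKV")
    assert score == 14  # BLOSUM62 diagonal: M=5, K=5, V=4
    assert aln_len == 3


def test_self_alignment_is_optimal():
    rng = np.random.default_rng(2)
    query = "".join(np.array(list(AA))[rng.integers(0, 20, size=30)])
    self_score, _ = local_align(query, query)
    for _ in range(5):
        other = "".join(np.array(list(AA))[rng.integers(0, 20, size=30)])
        assert local_align(query, other)[0] <= self_score


def test_local_align_matches_exhaustive_dp():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(4)
    for _ in range(15):
        q = "".join(np.array(list(AA))[rng.integers(0, 20, size=int(rng.integers(5, 21)))])
        s = "".join(np.array(list(AA))[rng.integers(0, 20, size=int(rng.integers(5, 21)))])
        score, _ = local_align(q, s)
        assert score == pytest.approx(sw_affine_oracle(q, s, blosum))


def test_evalue_properties():
    assert evalue(40, 100, 200, 0.041, 0.267) == pytest.approx(
        2 * evalue(40, 100, 100, 0.041, 0.267)
    )
    assert evalue(41, 100, 100, 0.041, 0.267) < evalue(40, 100, 100, 0.041, 0.267)
    # closed form at the documented protein-stage constants
    expected = 0.041 * 1e4 * math.exp(-10.68)
    assert evalue(40, 100, 100, 0.041, 0.267) == pytest.approx(expected)
    assert expected == pytest.approx(0.0094302, rel=1e-4)
    with pytest.raises(ValidationError):
        evalue(10, 5, 5, 0.0, 0.267)


def test_threshold_strictness():
    cfg = PipelineConfig()
    exact_half = HomologyHit("q", "s", 50.0, 0.1, aln_len=50, query_len=100)
    assert not _passes(exact_half, cfg)  # > 50% means 50% is rejected
    assert _passes(HomologyHit("q", "s", 50.0, 0.1, 51, 100), cfg)
    assert not _passes(HomologyHit("q", "s", 50.0, 0.5, 51, 100), cfg)  # E < 0.5 strict


def test_cascade_recovers_hidden_genes_and_rejects_decoys(bundle, denovo_calls):
    hidden_ids = {h.locus_id for h in bundle.truth.hidden_genes}
    protein_hits = {
        c.hit.subject_id for c in denovo_calls if c.status == "de_novo_protein"
    }
    assert protein_hits == hidden_ids
    # the only peaks annotated against the protein reference are the ones
    # over hidden genes: terminal, end-decoy and intergenic decoy peaks stay
    # unknown
    for call in denovo_calls:
        if call.status == "de_novo_protein":
            iv = call.peak.interval
            assert any(
                h.interval.chrom == iv.chrom
                and iv.start <= h.interval.start
                and iv.end >= h.interval.end
                for h in bundle.truth.hidden_genes
            )
        else:
            assert call.status == "still_unknown"


def test_nucleotide_fallback(bundle):
    """A peak whose ORF matches no protein still annotates when its DNA
    matches a nucleotide record; complete-genome records are excluded."""
    h = bundle.truth.hidden_genes[0]
    iv = h.interval
    peak = Peak(Interval(iv.chrom, iv.start - 50, iv.end + 50), "IP1")
    dna = bundle.sequences[iv.chrom][iv.start : iv.end]
    calls = annotate_unknown_peaks(
        [peak], bundle.sequences, {}, {"nt1": dna}, PipelineConfig()
    )
    assert calls[0].status == "de_novo_nucleotide"
    assert calls[0].hit.subject_id == "nt1"
    calls = annotate_unknown_peaks(
        [peak], bundle.sequences, {}, {"nt1": dna}, PipelineConfig(),
        nucl_db_complete_genomes={"nt1"},
    )
    assert calls[0].status == "still_unknown"


def test_filter_monotonicity(bundle):
    """Loosening either threshold never annotates fewer peaks."""
    peaks = []
    for h in bundle.truth.hidden_genes[:4]:
        iv = h.interval
        peaks.append(Peak(Interval(iv.chrom, iv.start - 60, iv.end + 60), "IP1"))
    base_cfg = PipelineConfig()
    loose_e = PipelineConfig(evalue_max=10.0)
    loose_len = PipelineConfig(aln_len_min=0.1)

    def n_annotated(cfg):
        calls = annotate_unknown_peaks(peaks, bundle.sequences, bundle.proteins, {}, cfg)
        return sum(c.status != "still_unknown" for c in calls)

    base = n_annotated(base_cfg)
    assert n_annotated(loose_e) >= base
    assert n_annotated(loose_len) >= base


def test_blast_tabular_adapter(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("q1\ts1\t80\t1e-10\t100.5\nq1\ts2\t40\t0.2\t30.0\n")
    hits = hits_from_blast_tab(str(path), {"q1": 100})
    assert hits[0].subject_id == "s1" and hits[0].score == 100.5
    assert hits[1].evalue == 0.2 and hits[1].query_len == 100


def test_builtin_backend_contract(bundle):
    backend = BuiltinSearchBackend(protein=True)
    query = bundle.proteins[bundle.truth.hidden_genes[0].locus_id]
    hits = backend.search("q", query, bundle.proteins)
    assert hits[0].subject_id == bundle.truth.hidden_genes[0].locus_id
    assert hits == sorted(hits, key=lambda h: (-h.score, h.subject_id))
    for h in hits:
        assert h.evalue >= 0 and h.query_len == len(query)
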