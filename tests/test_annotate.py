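"""Peak categorization, replicate consensus and composition statistics."""

import numpy as np
import pytest

from merochip.annotate import (
    categorize_peaks,
    compare_peak_distance_groups,
    consensus_targets,
    dedupe_targets,
    locus_overlap_fraction,
    nearest_feature_distance,
    target_composition,
)
from merochip.model import Feature, Interval, Peak, ValidationError


def _gene(chrom, start, end, locus):
    return Feature(Interval(chrom, start, end), locus, "gene")


def _peak(chrom, start, end, rep="IP1"):
    return Peak(Interval(chrom, start, end), rep)


@pytest.mark.parametrize(
    "peak, feature, expected",
    [
        ((100, 600), (200, 400), 1.0),  # peak contains the locus
        ((200, 400), (300, 500), 0.5),  # 100 / 200
        ((0, 100), (500, 600), 0.0),
    ],
)
def test_locus_overlap_fraction(peak, feature, expected):
    assert locus_overlap_fraction(
        _peak("chr1", *peak), _gene("chr1", *feature, "G")
    ) == pytest.approx(expected)


def test_exact_half_overlap_is_high_overlap():
    # the 50% threshold is inclusive
    (res,) = categorize_peaks(
        [_peak("chr1", 200, 400)], [_gene("chr1", 300, 500, "G1")], threshold=0.5
    )
    assert res.category == "high_overlap"
    assert res.overlap_fraction == pytest.approx(0.5)


def test_best_locus_wins_and_intergenic_is_unannotated():
    feats = [_gene("chr1", 100, 200, "A"), _gene("chr1", 220, 640, "B")]
    (res,) = categorize_peaks([_peak("chr1", 140, 350)], feats)
    assert res.matched_feature == "A"  # 60/100 beats 130/420
    assert res.category == "high_overlap"
    (res,) = categorize_peaks([_peak("chr1", 700, 800)], feats)
    assert res.category == "unannotated"
    assert res.matched_feature is None


def test_tie_breaks_by_position_then_id():
    feats = [_gene("chr1", 300, 400, "Z"), _gene("chr1", 100, 200, "A")]
    (res,) = categorize_peaks([_peak("chr1", 150, 350)], feats)
    # both loci half-covered: the earlier-starting locus wins
    assert res.matched_feature == "A"


def test_categorize_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    feats = []
    pos = 0
    for i in range(200):
        pos += int(rng.integers(20, 120))
        length = int(rng.integers(30, 250))
        feats.append(_gene("chr1", pos, pos + length, f"G{i}"))
        pos += length
    peaks = []
    for _ in range(300):
        start = int(rng.integers(0, pos))
        peaks.append(_peak("chr1", start, start + int(rng.integers(10, 400))))
    results = categorize_peaks(peaks, feats, threshold=0.5)
    for peak, res in zip(peaks, results):
        fracs = [(locus_overlap_fraction(peak, f), f.locus_id) for f in feats]
        best_frac = max(f for f, _ in fracs)
        if best_frac == 0:
            assert res.category == "unannotated"
        else:
            best_ids = {i for f, i in fracs if f == best_frac}
            assert res.matched_feature in best_ids
            assert res.overlap_fraction == pytest.approx(best_frac)
            expected = "high_overlap" if best_frac >= 0.5 else "low_overlap"
            assert res.category == expected


def test_dedupe_targets():
    feats = [_gene("chr1", 0, 100, "g1"), _gene("chr1", 200, 300, "g2")]
    annotated = categorize_peaks(
        [_peak("chr1", 0, 100), _peak("chr1", 10, 90), _peak("chr1", 200, 300)], feats
    )
    assert dedupe_targets(annotated) == {"g1", "g2"}
    assert dedupe_targets([]) == set()


def test_consensus_rules():
    sets = [{"g1", "g2"}, {"g2", "g3"}, {"g2"}]
    assert consensus_targets(sets, 2) == {"g2"}
    assert consensus_targets(sets, 1) == {"g1", "g2", "g3"}
    assert consensus_targets(sets, 3) == {"g2"} & {"g2", "g3"} & {"g2"}
    with pytest.raises(ValidationError):
        consensus_targets(sets, 4)
    with pytest.raises(ValidationError):
        consensus_targets([], 1)


def test_consensus_is_antitone_in_min_replicates():
    rng = np.random.default_rng(11)
    sets = [
        {f"g{i}" for i in rng.integers(0, 50, size=30)} for _ in range(5)
    ]
    previous = consensus_targets(sets, 1)
    for k in range(2, 6):
        current = consensus_targets(sets, k)
        assert current <= previous
        previous = current


def test_target_composition_rounding():
    feats = [_gene("chr1", i * 10, i * 10 + 5, f"g{i}") for i in range(6108)]
    consensus = {f"g{i}" for i in range(242)}
    comp = target_composition(consensus, feats)
    assert comp["n_genes"] == 242
    assert comp["pct_genes"] == 4  # 3.96% rounds half-up to 4
    assert comp["pct_repeats"] == 0
    assert target_composition(set(), feats)["pct_genes"] == 0
    reps = [Feature(Interval("chr1", 0, 10), "r1", "repeat")]
    assert target_composition({"r1"}, reps)["pct_repeats"] == 100
    with pytest.raises(ValidationError):
        target_composition({"nope"}, feats)


def test_nearest_feature_distance():
    feats = [_gene("chr1", 800, 900, "A"), _gene("chr1", 1250, 1300, "B")]
    peaks = [
        _peak("chr1", 850, 950),  # overlaps A
        _peak("chr1", 1000, 1100),  # 100 from A, 150 from B
        _peak("chr2", 0, 10),  # chromosome without features
    ]
    assert nearest_feature_distance(peaks, feats) == [0, 100, None]


def test_nearest_distance_matches_min_oracle():
    rng = np.random.default_rng(5)
    feats = [_gene("chr1", int(s), int(s) + 50, f"g{i}")
             for i, s in enumerate(sorted(rng.integers(0, 5000, size=40) * 2))]
    peaks = [_peak("chr1", int(s), int(s) + 30) for s in rng.integers(0, 10000, size=50)]
    result = nearest_feature_distance(peaks, feats)
    for peak, d in zip(peaks, result):
        gaps = [
            max(f.interval.start - peak.interval.end, peak.interval.start - f.interval.end, 0)
            for f in feats
        ]
        assert d == min(gaps)


def test_compare_distance_groups():
    out = compare_peak_distance_groups([0, 100], [0, 100])
    assert out["meanA"] == out["meanB"] == 50
    assert out["seA"] == pytest.approx(50)
    with pytest.raises(ValidationError):
        compare_peak_distance_groups([], [1.0])


def test_hidden_vs_decoy_peak_distances_are_similar(bundle):
    """Peaks over hidden genes and decoy intergenic peaks sit at comparable
    distances from annotated features, by construction."""
    from merochip.annotate import categorize_peaks as cat

    hidden = {
        (h.interval.chrom, h.interval.start, h.interval.end)
        for h in bundle.truth.hidden_genes
    }

    def is_hidden(peak):
        return any(
            c == peak.interval.chrom and peak.interval.start <= s and peak.interval.end >= e
            for c, s, e in hidden
        )

    unann = [
        a.peak
        for a in cat(bundle.peaks["IP1"], bundle.features)
        if a.category == "unannotated"
    ]
    dists = nearest_feature_distance(unann, bundle.features)
    grp_hidden = [d for p, d in zip(unann, dists) if is_hidden(p) and d is not None]
    grp_other = [
        d
        for p, d in zip(unann, dists)
        if not is_hidden(p) and d is not None and d < 2000  # interior peaks only
    ]
    out = compare_peak_distance_groups(grp_hidden, grp_other)
    assert abs(out["meanA"] - out["meanB"]) < 500
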