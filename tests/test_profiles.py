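"""Scale-regions matrices, k-means clustering and expression summaries."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import pandas as pd

from merochip.model import CoverageTrack, Feature, Interval, PipelineConfig, ValidationError
from merochip.profiles import (
    ClusterResult,
    ProfileMatrix,
    average_matrices,
    build_profile_matrix,
    cluster_expression_summary,
    kmeans_cluster,
    mean_target_profile,
)


def _tracks(values_ip, values_in, bin_bp=50):
    ip = CoverageTrack(bin_bp, {"chr1": np.asarray(values_ip, float)})
    inp = CoverageTrack(bin_bp, {"chr1": np.asarray(values_in, float)})
    return ip, inp


def _gene(start, end, strand="+", locus="G1"):
    return Feature(Interval("chr1", start, end, strand), locus, "gene")


def test_flat_tracks_give_unit_matrix():
    ip, inp = _tracks(np.full(200, 3.0), np.full(200, 3.0))
    m = build_profile_matrix(ip, inp, [_gene(2000, 3000)], PipelineConfig())
    assert m.values.shape == (1, 30)  # 10 + 10 + 10 columns at defaults
    assert np.allclose(m.values, 1.0)


def test_minus_strand_row_is_the_mirrored_plus_row():
    rng = np.random.default_rng(0)
    vals = rng.random(200) + 0.5
    ip, inp = _tracks(vals, np.ones(200))
    cfg = PipelineConfig()
    plus = build_profile_matrix(ip, inp, [_gene(2000, 3470, "+")], cfg)
    minus = build_profile_matrix(ip, inp, [_gene(2000, 3470, "-")], cfg)
    assert np.allclose(minus.values[0], plus.values[0][::-1])


def test_scale_invariance_with_zero_pseudocount():
    rng = np.random.default_rng(1)
    vals_ip = rng.random(200) + 0.5
    vals_in = rng.random(200) + 0.5
    cfg = PipelineConfig(pseudocount=0.0)
    m1 = build_profile_matrix(*_tracks(vals_ip, vals_in), [_gene(2000, 3000)], cfg)
    m2 = build_profile_matrix(*_tracks(3 * vals_ip, 3 * vals_in), [_gene(2000, 3000)], cfg)
    assert np.allclose(m1.values, m2.values)


def test_edge_regions_are_zero_padded_and_flagged():
    ip, inp = _tracks(np.ones(200), np.ones(200))
    m = build_profile_matrix(ip, inp, [_gene(100, 700)], PipelineConfig())
    assert "G1" in m.truncated
    assert m.values[0, 0] == 0.0  # upstream flank reaches before the chromosome


def test_kmeans_recovers_archetypes_from_duplicated_rows():
    rng = np.random.default_rng(5)
    body = np.r_[np.ones(10), np.full(10, 4.0), np.ones(10)]
    down = np.r_[np.ones(10), np.ones(10), np.full(10, 4.0)]
    up = np.r_[np.full(10, 4.0), np.ones(10), np.ones(10)]
    flat = np.ones(30)
    rows, labels = [], []
    for arche, profile in (("body", body), ("down", down), ("up", up), ("none", flat)):
        reps = 12 if arche != "none" else 60
        for _ in range(reps):
            rows.append(profile + rng.normal(0, 0.1, 30))
            labels.append(arche)
    matrix = ProfileMatrix(
        [f"r{i}" for i in range(len(rows))], np.clip(np.array(rows), 0, None), 50, 500, 500
    )
    result = kmeans_cluster(matrix, 4, seed=0)
    pred = [result.assignment[r] for r in matrix.rows]
    assert adjusted_rand_score(labels, pred) >= 0.9
    # cluster 1 is the body-enriched cluster by construction of the labels
    body_rows = {r for r, l in zip(matrix.rows, labels) if l == "body"}
    assert result.members(1) == body_rows


def test_kmeans_determinism_and_degenerate_cases():
    matrix = ProfileMatrix(["a", "b", "c"], np.ones((3, 30)), 50, 500, 500)
    res = kmeans_cluster(matrix, 1, seed=0)
    assert res.inertia == pytest.approx(0.0)
    assert set(res.assignment.values()) == {1}
    rng = np.random.default_rng(8)
    m2 = ProfileMatrix(
        [f"r{i}" for i in range(20)], rng.random((20, 30)), 50, 500, 500
    )
    r1 = kmeans_cluster(m2, 3, seed=11)
    r2 = kmeans_cluster(m2, 3, seed=11)
    assert r1.assignment == r2.assignment
    with pytest.raises(ValidationError):
        kmeans_cluster(m2, 0, seed=0)
    with pytest.raises(ValidationError):
        kmeans_cluster(m2, 21, seed=0)


def test_cluster_relabelling_is_seed_stable_on_separated_data():
    """Membership sets survive a different k-means seed because clusters are
    renamed by body enrichment, not by raw label."""
    rng = np.random.default_rng(3)
    body = np.r_[np.ones(10), np.full(10, 4.0), np.ones(10)]
    flat = np.ones(30)
    rows = [body + rng.normal(0, 0.05, 30) for _ in range(10)]
    rows += [flat + rng.normal(0, 0.05, 30) for _ in range(30)]
    matrix = ProfileMatrix(
        [f"r{i}" for i in range(40)], np.clip(np.array(rows), 0, None), 50, 500, 500
    )
    a = kmeans_cluster(matrix, 2, seed=0)
    b = kmeans_cluster(matrix, 2, seed=123)
    assert a.members(1) == b.members(1)


def test_cluster_expression_summary_cases():
    result = ClusterResult(
        {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2}, np.ones((2, 30)), 0, 0.0
    )
    fpkm = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0, "e": 1.0, "f": 1.0})
    out = cluster_expression_summary(result, fpkm)
    assert out["clusters"][1] == {"mean_fpkm": 1.0, "se": 0.0, "n": 3}
    t_p = out["tests"][(1, 2)]
    assert t_p["t"] == pytest.approx(0.0)
    assert t_p["p"] == pytest.approx(1.0)


def test_cluster_expression_skips_tiny_clusters_and_missing_fpkm():
    result = ClusterResult({"a": 1, "b": 2, "c": 2}, np.ones((2, 30)), 0, 0.0)
    fpkm = pd.Series({"a": 1.0, "b": 2.0})  # c has no FPKM
    out = cluster_expression_summary(result, fpkm)
    assert out["n_missing_fpkm"] == 1
    assert out["tests"] == {}  # both clusters end with n < 2


def test_mean_target_profile():
    matrix = ProfileMatrix(["a", "b", "c"], np.arange(90, dtype=float).reshape(3, 30),
                           50, 500, 500)
    assert np.allclose(mean_target_profile(matrix, {"a"}), matrix.values[0])
    assert np.allclose(
        mean_target_profile(matrix, {"a", "c"}), matrix.values[[0, 2]].mean(axis=0)
    )
    with pytest.raises(ValidationError):
        mean_target_profile(matrix, set())
    with pytest.raises(ValidationError):
        mean_target_profile(matrix, {"zzz"})


def test_target_profile_covers_body_and_both_flanks(bundle, cfg):
    """Averaged over all targets, enrichment stands above background over
    the body and both 0.5 kb flanks."""
    matrix = average_matrices(
        [
            build_profile_matrix(bundle.tracks[r], bundle.tracks["input"],
                                 bundle.gene_features, cfg)
            for r in ("IP1", "IP2", "IP3")
        ]
    )
    targets = bundle.truth.target_genes
    prof = mean_target_profile(matrix, targets)
    nontargets = {f.locus_id for f in bundle.gene_features} - targets
    background = mean_target_profile(matrix, nontargets)
    assert prof.mean() > 1.3 * background.mean()
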