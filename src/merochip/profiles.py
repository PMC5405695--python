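"""Input-normalized scale-regions profile matrices and their clustering.

Each region contributes one row: a fixed number of upstream-flank bins, a
gene body linearly resampled to a fixed width (500 bp in 50 bp bins by
default), and downstream-flank bins, always oriented 5'->3' (minus-strand
rows are reversed). The per-bin value is the enrichment ratio
``(IP + pseudocount) / (input + pseudocount)``. Rows are clustered with
standard k-means and the clusters relabelled by descending mean body
enrichment, so cluster 1 is always the body-enriched cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression import student_t
from .model import CoverageTrack, Feature, PipelineConfig, ValidationError


@dataclass
class ProfileMatrix:
    rows: List[str]
    values: np.ndarray  # (n_rows, n_flank + n_body + n_flank)
    bin_bp: int
    flank_bp: int
    body_bp: int
    truncated: Set[str] = field(default_factory=set)  # rows zero-padded at a chromosome edge
    short_regions: Set[str] = field(default_factory=set)  # regions shorter than one bin

    def __post_init__(self) -> None:
        if len(self.rows) != len(set(self.rows)):
            raise ValidationError("row ids must be unique")
        if self.values.shape != (len(self.rows), self.n_columns):
            raise ValidationError("matrix shape inconsistent with bin layout")
        if np.any(self.values < 0):
            raise ValidationError("profile values must be non-negative")

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.bin_bp

    @property
    def n_body_bins(self) -> int:
        return self.body_bp // self.bin_bp

    @property
    def n_columns(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins

    @property
    def body_slice(self) -> slice:
        return slice(self.n_flank_bins, self.n_flank_bins + self.n_body_bins)

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"up_{i + 1}" for i in range(self.n_flank_bins)]
            + [f"body_{i + 1}" for i in range(self.n_body_bins)]
            + [f"down_{i + 1}" for i in range(self.n_flank_bins)]
        )
        return pd.DataFrame(self.values, index=self.rows, columns=cols)


def _ratio_tracks(
    ip: CoverageTrack, input_track: CoverageTrack, pseudocount: float
) -> Dict[str, np.ndarray]:
    if ip.bin_size != input_track.bin_size:
        raise ValidationError("IP and input tracks have different bin sizes")
    if set(ip.data) != set(input_track.data):
        raise ValidationError("IP and input tracks cover different chromosomes")
    out = {}
    for chrom in ip.data:
        a, b = ip.data[chrom], input_track.data[chrom]
        if a.shape != b.shape:
            raise ValidationError(f"bin count mismatch on {chrom}")
        denom = b + pseudocount
        if np.any(denom <= 0):
            raise ValidationError(
                "zero input bins with pseudocount 0: ratio undefined"
            )
        out[chrom] = (a + pseudocount) / denom
    return out


def _sample(ratio: np.ndarray, positions: np.ndarray, bin_bp: int) -> np.ndarray:
    """Linear interpolation of bin values at arbitrary bp positions.

    Bin values sit at bin centers; positions beyond the chromosome are
    zero (the caller flags the row as truncated).
    """
    centers = (np.arange(len(ratio)) + 0.5) * bin_bp
    return np.interp(positions, centers, ratio, left=0.0, right=0.0) * (
        (positions >= 0) & (positions < len(ratio) * bin_bp)
    )


def build_profile_matrix(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    regions: Sequence[Feature],
    cfg: Optional[PipelineConfig] = None,
) -> ProfileMatrix:
    """Scale-regions matrix of input-normalized enrichment over regions."""
    cfg = cfg or PipelineConfig()
    ratio = _ratio_tracks(ip, input_track, cfg.pseudocount)
    n_flank = cfg.flank_bp // cfg.bin_bp
    n_body = cfg.body_bp // cfg.bin_bp
    rows: List[str] = []
    mat = np.zeros((len(regions), 2 * n_flank + n_body))
    truncated: Set[str] = set()
    short: Set[str] = set()
    for r, feat in enumerate(regions):
        iv = feat.interval
        vec = ratio[iv.chrom]
        chrom_len_bins = len(vec)
        # flank sample positions at native bin_bp pitch, bodies resampled
        up = iv.start - cfg.flank_bp + (np.arange(n_flank) + 0.5) * cfg.bin_bp
        down = iv.end + (np.arange(n_flank) + 0.5) * cfg.bin_bp
        body_pitch = iv.width / n_body
        body = iv.start + (np.arange(n_body) + 0.5) * body_pitch
        if iv.width < cfg.bin_bp:
            short.add(feat.locus_id)
        if iv.start - cfg.flank_bp < 0 or iv.end + cfg.flank_bp > chrom_len_bins * ip.bin_size:
            truncated.add(feat.locus_id)
        profile = np.concatenate(
            [
                _sample(vec, up, ip.bin_size),
                _sample(vec, body, ip.bin_size),
                _sample(vec, down, ip.bin_size),
            ]
        )
        if iv.strand == "-":
            profile = profile[::-1]
        mat[r] = profile
        rows.append(feat.locus_id)
    return ProfileMatrix(rows, mat, cfg.bin_bp, cfg.flank_bp, cfg.body_bp, truncated, short)


def average_matrices(matrices: Sequence[ProfileMatrix]) -> ProfileMatrix:
    """Pool replicate matrices by averaging their normalized values."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.rows != first.rows or m.values.shape != first.values.shape:
            raise ValidationError("matrices must share rows and layout")
    values = np.mean([m.values for m in matrices], axis=0)
    return ProfileMatrix(
        list(first.rows), values, first.bin_bp, first.flank_bp, first.body_bp,
        set().union(*(m.truncated for m in matrices)),
        set().union(*(m.short_regions for m in matrices)),
    )


@dataclass
class ClusterResult:
    assignment: Dict[str, int]  # locus -> 1..k; cluster 1 is body-enriched
    centroids: np.ndarray  # (k, n_columns), in relabelled order
    seed: int
    inertia: float

    def members(self, cluster: int) -> Set[str]:
        return {locus for locus, c in self.assignment.items() if c == cluster}


def kmeans_cluster(matrix: ProfileMatrix, k: int, seed: int = 0) -> ClusterResult:
    """k-means (k-means++ init, 10 restarts, fixed seed) on raw profiles.

    Cluster labels are reported sorted by descending mean body enrichment
    (ties by descending downstream-flank mean), so "cluster 1" is the
    body-enriched cluster.
    """
    n = len(matrix.rows)
    if k < 1 or k > n:
        raise ValidationError(f"k={k} invalid for {n} rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(matrix.values)
    body = matrix.body_slice
    down = slice(matrix.n_flank_bins + matrix.n_body_bins, matrix.n_columns)
    order = sorted(
        range(k),
        key=lambda c: (
            -km.cluster_centers_[c, body].mean(),
            -km.cluster_centers_[c, down].mean(),
        ),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignment = {locus: relabel[int(c)] for locus, c in zip(matrix.rows, labels)}
    centroids = km.cluster_centers_[order]
    return ClusterResult(assignment, centroids, seed, float(km.inertia_))


def cluster_expression_summary(
    result: ClusterResult, fpkm: pd.Series, equal_var: bool = True
) -> dict:
    """Per-cluster FPKM mean/SE/n and pairwise Student t-tests.

    Loci without an FPKM value are excluded (their count is reported);
    clusters with fewer than two remaining members get no SE and no tests.
    """
    k = int(max(result.assignment.values()))
    groups: Dict[int, np.ndarray] = {}
    n_missing = 0
    for c in range(1, k + 1):
        members = sorted(result.members(c))
        vals = [float(fpkm[m]) for m in members if m in fpkm.index]
        n_missing += len(members) - len(vals)
        groups[c] = np.asarray(vals)
    per_cluster = {}
    for c, vals in groups.items():
        n = len(vals)
        per_cluster[c] = {
            "mean_fpkm": float(vals.mean()) if n else float("nan"),
            "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            "n": n,
        }
    tests = {}
    for a in range(1, k + 1):
        for b in range(a + 1, k + 1):
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                continue
            t, p = student_t(groups[a], groups[b], equal_var=equal_var)
            tests[(a, b)] = {"t": t, "p": p}
    return {"clusters": per_cluster, "tests": tests, "n_missing_fpkm": n_missing}


def mean_target_profile(matrix: ProfileMatrix, ids: Set[str]) -> np.ndarray:
    """Column-wise mean profile over the selected rows."""
    if not ids:
        raise ValidationError("empty selection")
    missing = ids - set(matrix.rows)
    if missing:
        raise ValidationError(f"ids not in matrix: {sorted(missing)[:5]}")
    index = [i for i, r in enumerate(matrix.rows) if r in ids]
    return matrix.values[index].mean(axis=0)
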