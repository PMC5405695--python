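"""Core domain types and interval arithmetic.

All coordinates are 0-based half-open on the forward strand, everywhere in
the package; GFF3's 1-based closed convention is converted at the I/O
boundary (:mod:`merochip.io`). Abutting intervals (``a.end == b.start``) do
not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval: 0-based half-open ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded). Strand is carried
    for profile orientation only; overlap arithmetic ignores it.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Feature:
    """An annotated locus: a gene or a repetitive element."""

    interval: Interval
    locus_id: str
    feature_class: str  # "gene" | "repeat"
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if self.feature_class not in ("gene", "repeat"):
            raise ValidationError(
                f"feature_class must be 'gene' or 'repeat', got {self.feature_class!r}"
            )


@dataclass(frozen=True)
class Peak:
    """A scored ChIP interval from one replicate (consumed, not called here)."""

    interval: Interval
    replicate_id: str
    score: Optional[float] = None


class GenomeModel:
    """Chromosome names, lengths and optional terminal telomere spans.

    Telomere spans are lengths in bp measured inward from the respective
    chromosome end; they must lie within ``[0, length)``.
    """

    def __init__(
        self,
        chromosomes: Sequence[Tuple[str, int]],
        telomeres: Optional[Mapping[str, Tuple[int, int]]] = None,
    ) -> None:
        names = [c for c, _ in chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        for name, length in chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")
        self.chromosomes: List[Tuple[str, int]] = [(c, int(l)) for c, l in chromosomes]
        self._lengths: Dict[str, int] = {c: int(l) for c, l in chromosomes}
        self.telomeres: Dict[str, Tuple[int, int]] = {}
        for chrom, (t5, t3) in (telomeres or {}).items():
            length = self.length_of(chrom)
            if not (0 <= t5 < length and 0 <= t3 < length):
                raise ValidationError(f"telomere spans out of range on {chrom}")
            self.telomeres[chrom] = (int(t5), int(t3))

    @property
    def names(self) -> List[str]:
        return [c for c, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def validate_interval(self, iv: Interval) -> None:
        length = self.length_of(iv.chrom)
        if iv.end > length:
            raise ValidationError(
                f"interval [{iv.start}, {iv.end}) exceeds {iv.chrom} length {length}"
            )


class CoverageTrack:
    """Dense, binned, non-negative coverage: one vector per chromosome.

    Bin ``i`` of chromosome ``c`` covers ``[i*bin_size, (i+1)*bin_size)``;
    the last bin may be partial. Vector length is ``ceil(length / bin_size)``.
    """

    def __init__(self, bin_size: int, data: Mapping[str, np.ndarray]) -> None:
        if bin_size < 1:
            raise ValidationError("bin_size must be >= 1")
        self.bin_size = int(bin_size)
        self.data: Dict[str, np.ndarray] = {}
        for chrom, vec in data.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"track for {chrom} must be 1-D")
            if np.any(arr < 0):
                raise ValidationError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    @classmethod
    def zeros(cls, genome: GenomeModel, bin_size: int) -> "CoverageTrack":
        return cls(
            bin_size,
            {
                chrom: np.zeros(-(-length // bin_size))
                for chrom, length in genome.chromosomes
            },
        )

    def concatenated(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        names = list(order) if order is not None else sorted(self.data)
        return np.concatenate([self.data[c] for c in names])


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, with the study's stated defaults.

    overlap_threshold
        Minimum fraction of a locus length a peak must cover to count as a
        high-overlap annotation (inclusive).
    aln_len_min / evalue_max
        Homology acceptance: alignment length strictly greater than
        ``aln_len_min``  x query length AND E-value strictly below
        ``evalue_max``.
    flank_bp / body_bp / bin_bp
        Scale-regions geometry: native-scale flanks and the fixed width the
        gene body is resampled to, in bins of ``bin_bp``.
    min_replicates
        Replicate consensus rule (2 of 3).
    k_genes / k_repeats
        k-means cluster counts for gene and repeat profile matrices.
    go_min_entries / alpha
        GO terms need at least this many target genes to be tested;
        significance is adjusted p < alpha.
    end_distance_bp
        A chromosome end is H3K27me3-enriched when the nearest domain lies
        within this distance.
    merge_gap_bp
        Peaks closer than this are merged into one domain.
    effective_db_residues
        Effective search-space size for E-values, emulating a search against
        a comprehensive sequence collection (the BLAST ``-dbsize``
        convention) rather than the handful of local records.
    """

    overlap_threshold: float = 0.5
    aln_len_min: float = 0.5
    evalue_max: float = 0.5
    flank_bp: int = 500
    body_bp: int = 500
    bin_bp: int = 50
    min_replicates: int = 2
    k_genes: int = 4
    k_repeats: int = 3
    go_min_entries: int = 5
    alpha: float = 0.05
    end_distance_bp: int = 2000
    merge_gap_bp: int = 500
    pseudocount: float = 1.0
    min_orf_aa: int = 25
    effective_db_residues: float = 1e8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap_threshold", "aln_len_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        for name in (
            "flank_bp",
            "body_bp",
            "bin_bp",
            "min_replicates",
            "k_genes",
            "k_repeats",
            "go_min_entries",
            "min_orf_aa",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.evalue_max <= 0 or self.pseudocount < 0:
            raise ValidationError("evalue_max must be > 0 and pseudocount >= 0")


def overlap_bp(a: Interval, b: Interval, genome: Optional[GenomeModel] = None) -> int:
    """Overlap in bp between two intervals; 0 when chromosomes differ.

    Half-open semantics: abutting intervals do not overlap. When a
    ``genome`` is given, both intervals are validated against it.
    """
    if genome is not None:
        genome.validate_interval(a)
        genome.validate_interval(b)
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def union_covered_bp(intervals: Iterable[Interval]) -> int:
    """Total bp covered by the union of intervals (overlaps counted once)."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def genome_coverage_stats(peaks: Sequence[Peak], genome: GenomeModel) -> dict:
    """Genome-wide peak statistics: union coverage fraction, mean width, count.

    The covered fraction uses the union of peak intervals so overlapping
    peaks are counted once; the mean width is over the raw peaks. With no
    peaks the mean width is reported as 0.
    """
    if not genome.chromosomes:
        raise ValidationError("empty genome")
    for p in peaks:
        genome.validate_interval(p.interval)
    n = len(peaks)
    if n == 0:
        return {"fraction_covered": 0.0, "mean_peak_width": 0.0, "n_peaks": 0}
    covered = union_covered_bp(p.interval for p in peaks)
    mean_width = float(np.mean([p.interval.width for p in peaks]))
    return {
        "fraction_covered": covered / genome.total_length,
        "mean_peak_width": mean_width,
        "n_peaks": n,
    }


def replicate_correlation(a: CoverageTrack, b: CoverageTrack) -> float:
    """Pearson correlation between two tracks over concatenated bins.

    Raises :class:`ValidationError` for mismatched binning/chromosomes or a
    zero-variance track (the correlation is undefined there).
    """
    if a.bin_size != b.bin_size:
        raise ValidationError("tracks have different bin sizes")
    if set(a.data) != set(b.data):
        raise ValidationError("tracks cover different chromosomes")
    order = sorted(a.data)
    x = a.concatenated(order)
    y = b.concatenated(order)
    if x.shape != y.shape:
        raise ValidationError("tracks have different bin counts")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero-variance track: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
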