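"""Peak-to-feature annotation and the replicate-consensus target call.

A peak is matched to the single locus whose length it covers best; peaks
covering at least half of that locus (``overlap_threshold``, inclusive) are
"high overlap" annotations, anything with a positive but smaller fraction
is "low overlap", and peaks touching no locus are unannotated. Per
replicate, duplicate calls (two peaks spanning one locus) are collapsed,
and the final target set is the consensus of loci called in at least
``min_replicates`` of the replicates (2 of 3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np

from .model import Feature, Peak, ValidationError, overlap_bp

CATEGORIES = ("high_overlap", "low_overlap", "unannotated")


@dataclass
class AnnotatedPeak:
    peak: Peak
    category: str
    matched_feature: Optional[str]
    overlap_fraction: float


def locus_overlap_fraction(peak: Peak, feature: Feature) -> float:
    """Fraction of the *locus* length covered by this one peak; in [0, 1].

    Strand is ignored — the intersection is purely positional.
    """
    return overlap_bp(peak.interval, feature.interval) / feature.interval.width


def categorize_peaks(
    peaks: Sequence[Peak],
    features: Sequence[Feature],
    threshold: float = 0.5,
) -> List[AnnotatedPeak]:
    """Assign each peak its best-covered locus and an overlap category.

    The matched locus maximizes the per-peak locus overlap fraction; ties
    break on smaller feature start, then lexicographic locus id. The
    threshold is inclusive: a fraction exactly equal to it counts as
    high overlap.
    """
    by_chrom: Dict[str, List[Feature]] = {}
    for f in features:
        by_chrom.setdefault(f.interval.chrom, []).append(f)
    for fs in by_chrom.values():
        fs.sort(key=lambda f: (f.interval.start, f.locus_id))

    out: List[AnnotatedPeak] = []
    for peak in peaks:
        best: Optional[Feature] = None
        best_frac = 0.0
        for f in by_chrom.get(peak.interval.chrom, []):
            if f.interval.start >= peak.interval.end:
                break
            frac = locus_overlap_fraction(peak, f)
            if frac > best_frac:  # sort order implements the tie-break
                best, best_frac = f, frac
        if best is None or best_frac == 0.0:
            out.append(AnnotatedPeak(peak, "unannotated", None, 0.0))
        elif best_frac >= threshold:
            out.append(AnnotatedPeak(peak, "high_overlap", best.locus_id, best_frac))
        else:
            out.append(AnnotatedPeak(peak, "low_overlap", best.locus_id, best_frac))
    return out


def dedupe_targets(annotated: Iterable[AnnotatedPeak]) -> Set[str]:
    """Distinct high-overlap loci of one replicate (duplicates removed)."""
    return {
        a.matched_feature
        for a in annotated
        if a.category == "high_overlap" and a.matched_feature is not None
    }


def consensus_targets(
    replicate_sets: Sequence[Set[str]], min_replicates: int = 2
) -> Set[str]:
    """Loci appearing in at least ``min_replicates`` replicate target sets."""
    if not replicate_sets:
        raise ValidationError("need at least one replicate set")
    if min_replicates > len(replicate_sets) or min_replicates < 1:
        raise ValidationError(
            f"min_replicates {min_replicates} incompatible with "
            f"{len(replicate_sets)} replicates"
        )
    counts: Dict[str, int] = {}
    for s in replicate_sets:
        for locus in s:
            counts[locus] = counts.get(locus, 0) + 1
    return {locus for locus, n in counts.items() if n >= min_replicates}


def _pct_int(numerator: int, denominator: int) -> int:
    if denominator == 0:
        return 0
    ratio = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return int(ratio.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def target_composition(consensus: Set[str], features: Sequence[Feature]) -> dict:
    """Count consensus targets per feature class, with integer percentages
    of each class total (rounded half-up)."""
    by_id = {f.locus_id: f for f in features}
    unknown = consensus - set(by_id)
    if unknown:
        raise ValidationError(f"unknown consensus ids: {sorted(unknown)[:5]}")
    totals = {"gene": 0, "repeat": 0}
    hits = {"gene": 0, "repeat": 0}
    for f in features:
        totals[f.feature_class] += 1
        if f.locus_id in consensus:
            hits[f.feature_class] += 1
    return {
        "n_genes": hits["gene"],
        "pct_genes": _pct_int(hits["gene"], totals["gene"]),
        "n_repeats": hits["repeat"],
        "pct_repeats": _pct_int(hits["repeat"], totals["repeat"]),
    }


def nearest_feature_distance(
    peaks: Sequence[Peak], features: Sequence[Feature]
) -> List[Optional[int]]:
    """Unsigned gap distance from each peak to its closest feature.

    0 for any overlap; ``None`` when the peak's chromosome carries no
    feature at all (reported as missing, mirroring `bedtools closest`).
    """
    by_chrom: Dict[str, List[Feature]] = {}
    for f in features:
        by_chrom.setdefault(f.interval.chrom, []).append(f)
    out: List[Optional[int]] = []
    for p in peaks:
        fs = by_chrom.get(p.interval.chrom)
        if not fs:
            out.append(None)
            continue
        best = None
        for f in fs:
            if overlap_bp(p.interval, f.interval) > 0:
                best = 0
                break
            gap = max(f.interval.start - p.interval.end, p.interval.start - f.interval.end)
            best = gap if best is None else min(best, gap)
        out.append(best)
    return out


def compare_peak_distance_groups(
    group_a: Sequence[float], group_b: Sequence[float]
) -> dict:
    """Means and standard errors of two distance groups (no test — only the
    descriptive comparison is reported)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValidationError("both distance groups must be nonempty")

    def _stats(g: Sequence[float]):
        arr = np.asarray(g, dtype=float)
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        return float(arr.mean()), se

    mean_a, se_a = _stats(group_a)
    mean_b, se_b = _stats(group_b)
    return {"meanA": mean_a, "meanB": mean_b, "seA": se_a, "seB": se_b}
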