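"""GO-term enrichment of H3K27me3 target genes.

Per-term over-representation is tested with a one-sided Fisher exact test
(hypergeometric tail), adjusted within each GO sub-ontology with the
Benjamini-Yekutieli FDR procedure (valid under arbitrary dependence among
terms), after a minimum-entries filter. Term sets are flat: no GO-DAG
ancestor propagation is performed, matching a per-term singular enrichment
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import PipelineConfig, ValidationError

SUBONTOLOGIES = ("molecular_function", "biological_process", "cellular_component")


@dataclass
class GOAnnotationMap:
    """locus -> set of term ids, plus (name, subontology) metadata per term."""

    gene_terms: Dict[str, Set[str]]
    term_meta: Dict[str, Tuple[str, str]]

    def __post_init__(self) -> None:
        used = set().union(*self.gene_terms.values()) if self.gene_terms else set()
        missing = used - set(self.term_meta)
        if missing:
            raise ValidationError(f"terms without metadata: {sorted(missing)[:5]}")
        for term, (_name, sub) in self.term_meta.items():
            if sub not in SUBONTOLOGIES:
                raise ValidationError(f"unknown subontology {sub!r} for {term}")

    def terms_of(self, locus: str) -> Set[str]:
        return self.gene_terms.get(locus, set())


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    subontology: str
    n_target_with_term: int
    n_target: int
    n_ref_with_term: int
    n_ref: int
    p_raw: float
    p_adjusted: float
    significant: bool


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def annotation_coverage(ids: Iterable[str], go_map: GOAnnotationMap) -> dict:
    """Fraction of loci carrying at least one GO term, as a percentage with
    one decimal (rounded half-up)."""
    ids = list(ids)
    if not ids:
        raise ValidationError("empty id set")
    n_annotated = sum(1 for i in ids if go_map.terms_of(i))
    pct = _round_half_up(100.0 * n_annotated / len(ids), 1)
    return {"n_annotated": n_annotated, "n_total": len(ids), "pct": pct}


def fisher_term(n_target_with: int, n_target: int, n_ref_with: int, n_ref: int) -> float:
    """One-sided (over-representation) Fisher exact p-value.

    Equals the hypergeometric upper tail P(X >= n_target_with) when drawing
    ``n_target`` genes from a reference of ``n_ref`` genes of which
    ``n_ref_with`` carry the term.
    """
    ok = (
        0 <= n_target_with <= n_target <= n_ref
        and n_target_with <= n_ref_with <= n_ref
    )
    if not ok:
        raise ValidationError(
            f"inconsistent counts ({n_target_with}/{n_target}, {n_ref_with}/{n_ref})"
        )
    return float(hypergeom.sf(n_target_with - 1, n_ref, n_ref_with, n_target))


def by_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Yekutieli step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_by")
    return [float(x) for x in adjusted]


def enrich_all(
    target_ids: Iterable[str],
    reference_ids: Iterable[str],
    go_map: GOAnnotationMap,
    cfg: Optional[PipelineConfig] = None,
) -> List[EnrichmentRow]:
    """Test every sufficiently represented term, per sub-ontology.

    The minimum-entries filter (at least ``go_min_entries`` *target* genes
    carrying the term) is applied before testing, so filtered terms do not
    enter the multiple-testing family; BY adjustment is performed within
    each sub-ontology separately.
    """
    cfg = cfg or PipelineConfig()
    targets = set(target_ids)
    reference = set(reference_ids)
    if not reference:
        raise ValidationError("empty reference set")
    if not targets <= reference:
        raise ValidationError("target set must be a subset of the reference set")

    term_targets: Dict[str, int] = {}
    term_ref: Dict[str, int] = {}
    for locus in reference:
        for term in go_map.terms_of(locus):
            term_ref[term] = term_ref.get(term, 0) + 1
            if locus in targets:
                term_targets[term] = term_targets.get(term, 0) + 1

    rows: List[EnrichmentRow] = []
    for sub in SUBONTOLOGIES:
        family = sorted(
            t
            for t, k in term_targets.items()
            if k >= cfg.go_min_entries and go_map.term_meta[t][1] == sub
        )
        if not family:
            continue
        praw = [
            fisher_term(term_targets[t], len(targets), term_ref[t], len(reference))
            for t in family
        ]
        padj = by_adjust(praw)
        for t, p, q in zip(family, praw, padj):
            rows.append(
                EnrichmentRow(
                    term_id=t,
                    term_name=go_map.term_meta[t][0],
                    subontology=sub,
                    n_target_with_term=term_targets[t],
                    n_target=len(targets),
                    n_ref_with_term=term_ref[t],
                    n_ref=len(reference),
                    p_raw=p,
                    p_adjusted=q,
                    significant=q < cfg.alpha,
                )
            )
    rows.sort(key=lambda r: (r.subontology, r.p_adjusted, r.term_id))
    return rows
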