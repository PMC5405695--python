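"""Expression vs H3K27me3 status: the silencing-mark comparison.

Targets and non-targets are compared per feature class (genes and repeats
separately) with a two-sample equal-variance Student t-test on FPKM values
— the faithfulness choice here is the classical Student test; Welch's
correction is available behind ``equal_var=False``.
"""

from __future__ import annotations

import logging
from typing import Dict, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .model import Feature, ValidationError

logger = logging.getLogger(__name__)


def student_t(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Two-sample t-test that stays defined for degenerate (zero-variance)
    inputs: identical constant groups give t=0, p=1; constant groups with
    different means give an infinite statistic and p=0."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=equal_var)
    if np.isnan(t):
        if np.isclose(np.mean(a), np.mean(b)):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    return float(t), float(p)


def _group_stats(vals: np.ndarray) -> Dict[str, float]:
    n = len(vals)
    return {
        "mean": float(vals.mean()) if n else float("nan"),
        "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "n": n,
    }


def group_expression_comparison(
    targets: Set[str],
    features: Sequence[Feature],
    fpkm: pd.Series,
    equal_var: bool = True,
) -> Dict[str, dict]:
    """Target vs non-target FPKM comparison, one entry per feature class.

    Loci without an FPKM value are excluded (and counted in the log). A
    class with an empty group is skipped with a warning rather than tested.
    """
    out: Dict[str, dict] = {}
    for cls in ("gene", "repeat"):
        tgt, non = [], []
        n_missing = 0
        for f in features:
            if f.feature_class != cls:
                continue
            if f.locus_id not in fpkm.index:
                n_missing += 1
                continue
            (tgt if f.locus_id in targets else non).append(float(fpkm[f.locus_id]))
        if n_missing:
            logger.info("%s: %d loci without FPKM excluded", cls, n_missing)
        if not tgt or not non:
            logger.warning("%s: empty target or non-target group; comparison skipped", cls)
            continue
        tgt_arr, non_arr = np.asarray(tgt), np.asarray(non)
        t, p = student_t(tgt_arr, non_arr, equal_var=equal_var)
        entry = {
            "mean_target": _group_stats(tgt_arr)["mean"],
            "se_target": _group_stats(tgt_arr)["se"],
            "n_target": len(tgt),
            "mean_nontarget": _group_stats(non_arr)["mean"],
            "se_nontarget": _group_stats(non_arr)["se"],
            "n_nontarget": len(non),
            "t": float(t),
            "p": float(p),
            "n_missing_fpkm": n_missing,
        }
        out[cls] = entry
    return out


def class_expression_comparison(
    features: Sequence[Feature], fpkm: pd.Series
) -> Dict[str, dict]:
    """Mean/SE FPKM per feature class, irrespective of H3K27me3 status."""
    out: Dict[str, dict] = {}
    for cls in ("gene", "repeat"):
        vals = np.asarray(
            [
                float(fpkm[f.locus_id])
                for f in features
                if f.feature_class == cls and f.locus_id in fpkm.index
            ]
        )
        if len(vals) == 0:
            raise ValidationError(f"no FPKM values for class {cls!r}")
        out[cls] = _group_stats(vals)
    return out
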