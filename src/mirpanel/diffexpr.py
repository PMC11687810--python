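"""Per-miRNA differential expression between each case cohort and controls.

Group sizes in circulating-biomarker panels are too small to lean on
normality, so each miRNA is screened with a Shapiro-Wilk gate (recorded, not
acted on — the pipeline uses non-parametric tests throughout) and compared
with a two-sided Wilcoxon rank-sum test on normalized expression.  P-values
are adjusted with Benjamini-Hochberg within each cohort-vs-control
comparison, and effect sizes reported as median fold-differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import NormalizedMatrix, median_fold_difference

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class DEResult:
    assay_id: str
    cohort: str
    raw_p: float
    fdr_p: float
    median_fd: float
    direction: str  # up / down / ns
    normal: bool | None  # Shapiro-Wilk gate; None when undefined


def normality_gate(values_by_group: Mapping[str, Sequence[float]]) -> bool | None:
    """True when every group passes Shapiro-Wilk at p > 0.05.

    Undefined (None) when any group has fewer than 3 values; a constant
    group cannot be normal-tested and counts as failing the gate.
    """
    for vals in values_by_group.values():
        v = np.asarray(vals, dtype=float)
        if len(v) < 3:
            return None
        if np.ptp(v) == 0:
            return False
        if stats.shapiro(v).pvalue <= ALPHA:
            return False
    return True


def de_test(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Two-sided rank-sum p-value (exact for small tie-free groups)."""
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    pooled = np.concatenate([a, b])
    exact = max(len(a), len(b)) <= 8 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_table(
    normalized: NormalizedMatrix,
    groups: Mapping[str, str],
    cohorts: Mapping[str, str],
    cohort: str,
    alpha: float = ALPHA,
) -> list[DEResult]:
    """DE results for one case cohort against the pooled control group.

    ``groups`` maps sample_id -> case/control; ``cohorts`` maps sample_id ->
    cohort label.  Control assays are excluded (they self-normalize).  Rows
    are sorted by adjusted p.
    """
    values = normalized.non_control_values()
    case_ids = [s for s in values.index if cohorts.get(s) == cohort and groups.get(s) == "case"]
    ctrl_ids = [s for s in values.index if groups.get(s) == "control"]
    if not case_ids:
        logger.warning("cohort %r has no case samples; empty DE table", cohort)
        return []
    if not ctrl_ids:
        logger.warning("no control samples; empty DE table")
        return []

    rows = []
    for assay in values.columns:
        case_v = values.loc[case_ids, assay].to_numpy()
        ctrl_v = values.loc[ctrl_ids, assay].to_numpy()
        rows.append(
            {
                "assay_id": assay,
                "raw_p": de_test(case_v, ctrl_v),
                "median_fd": median_fold_difference(case_v, ctrl_v),
                "normal": normality_gate({"case": case_v, "control": ctrl_v}),
            }
        )
    fdr = bh_adjust([r["raw_p"] for r in rows])
    results = []
    for r, q in zip(rows, fdr):
        if q < alpha:
            direction = "up" if r["median_fd"] >= 1 else "down"
        else:
            direction = "ns"
        results.append(
            DEResult(
                assay_id=r["assay_id"],
                cohort=cohort,
                raw_p=r["raw_p"],
                fdr_p=float(q),
                median_fd=r["median_fd"],
                direction=direction,
                normal=r["normal"],
            )
        )
    results.sort(key=lambda r: (r.fdr_p, r.raw_p, r.assay_id))
    return results


def de_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"assay_id": r.assay_id, "cohort": r.cohort, "raw_p": r.raw_p,
             "fdr_p": r.fdr_p, "median_fd": r.median_fd, "direction": r.direction,
             "normal": r.normal}
            for r in results
        ]
    )
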