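"""Hemolysis screening for plasma miRNA samples.

Erythrocytes carry abundant miRNAs, so hemolysis during blood draw or
processing contaminates the circulating-miRNA profile.  Free hemoglobin is
read spectrophotometrically at 414 nm (the Soret peak); lipemia also raises
414 nm absorbance, which is corrected by the 414/375 nm ratio.

Samples are first admitted or rejected on absorbance alone, then classified
into ``non_hemolyzed``, ``hemolyzed`` and ``lipemic_non_hemolyzed``.  Each
assay is then screened for hemolysis dependence with two pieces of evidence:
the R^2 of an ordinary least-squares fit of Ct on 414 nm absorbance (lipemic
samples excluded — their 414 nm reading does not track hemoglobin), and a
two-sided rank-sum test of Ct between the hemolyzed group and the rest.  The
verdict is three-tier: ``affected`` (R^2 > 0.3 and p < 0.01), ``unaffected``
(R^2 < 0.2 and p > 0.05), else ``indeterminate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

NON_HEMOLYZED = "non_hemolyzed"
HEMOLYZED = "hemolyzed"
LIPEMIC = "lipemic_non_hemolyzed"

AFFECTED = "affected"
UNAFFECTED = "unaffected"
INDETERMINATE = "indeterminate"

# absorbance thresholds (absorbance units / unitless ratio)
A414_ADMIT_MAX = 1.5
RATIO_LIPEMIC = 1.4
A414_HEMOLYZED = 0.2

# verdict thresholds (strict inequalities)
R2_AFFECTED = 0.3
P_AFFECTED = 0.01
R2_UNAFFECTED = 0.2
P_UNAFFECTED = 0.05


@dataclass
class SampleHemolysisStatus:
    sample_id: str
    admitted: bool
    klass: str  # NON_HEMOLYZED / HEMOLYZED / LIPEMIC


@dataclass
class HemolysisVerdict:
    assay_id: str
    r2: float
    p: float
    klass: str
    reason: str = ""


def _check_absorbances(a414: float, a375: float) -> None:
    if not (a414 > 0 and a375 > 0):
        raise ValueError(f"absorbances must be positive, got a414={a414}, a375={a375}")


def admit_sample(a414: float, a375: float) -> bool:
    """A sample is usable if 414 nm < 1.5, or if the 414/375 ratio is < 1.4
    (high absorbance explained by lipemia rather than hemoglobin)."""
    _check_absorbances(a414, a375)
    return a414 < A414_ADMIT_MAX or (a414 / a375) < RATIO_LIPEMIC


def classify_sample(sample_id: str, a414: float, a375: float) -> SampleHemolysisStatus:
    """Three-way classification of an admitted sample.

    414 nm <= 0.2 is non-hemolyzed regardless of the ratio.  Above that the
    ratio decides: >= 1.4 means genuine hemoglobin (hemolyzed), < 1.4 means
    the absorbance is lipemic; such samples count with the non-hemolyzed
    group in the rank test but are excluded from the Ct-vs-absorbance
    regression.
    """
    _check_absorbances(a414, a375)
    admitted = admit_sample(a414, a375)
    if a414 <= A414_HEMOLYZED:
        klass = NON_HEMOLYZED
    elif a414 / a375 >= RATIO_LIPEMIC:
        klass = HEMOLYZED
    else:
        klass = LIPEMIC
    return SampleHemolysisStatus(sample_id=sample_id, admitted=admitted, klass=klass)


def classify_samples(
    absorbances: Mapping[str, tuple[float, float]]
) -> dict[str, SampleHemolysisStatus]:
    """Classify a mapping of sample_id -> (a414, a375)."""
    return {
        sid: classify_sample(sid, a414, a375)
        for sid, (a414, a375) in absorbances.items()
    }


def _verdict_class(r2: float, p: float) -> str:
    if r2 > R2_AFFECTED and p < P_AFFECTED:
        return AFFECTED
    if r2 < R2_UNAFFECTED and p > P_UNAFFECTED:
        return UNAFFECTED
    return INDETERMINATE


def mirna_hemolysis_association(
    assay_id: str,
    ct_values: Mapping[str, float],
    statuses: Mapping[str, SampleHemolysisStatus],
    a414: Mapping[str, float],
) -> HemolysisVerdict:
    """Dual-criteria hemolysis verdict for one assay.

    ``ct_values`` maps sample_id -> Ct for this assay; samples absent from
    ``statuses`` are ignored.  The regression pools cases and controls.
    """
    ids = [s for s in ct_values if s in statuses and statuses[s].admitted]
    reg_ids = [s for s in ids if statuses[s].klass != LIPEMIC]
    if len(reg_ids) < 3:
        raise ValueError(
            f"{assay_id}: need >= 3 samples for the regression, have {len(reg_ids)}"
        )
    x = np.array([a414[s] for s in reg_ids], dtype=float)
    y = np.array([ct_values[s] for s in reg_ids], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r2 = 0.0
    else:
        r2 = float(stats.linregress(x, y).rvalue ** 2)

    hem = [ct_values[s] for s in ids if statuses[s].klass == HEMOLYZED]
    non = [ct_values[s] for s in ids if statuses[s].klass != HEMOLYZED]
    if not hem or not non:
        return HemolysisVerdict(
            assay_id=assay_id, r2=r2, p=1.0, klass=INDETERMINATE,
            reason="no_hemolyzed_samples" if not hem else "no_non_hemolyzed_samples",
        )
    p = _ranksum_p(hem, non)
    return HemolysisVerdict(assay_id=assay_id, r2=r2, p=p, klass=_verdict_class(r2, p))


def _ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided rank-sum p: exact for small tie-free groups, else normal
    approximation with tie correction."""
    if np.ptp(list(a) + list(b)) == 0:
        return 1.0
    method = "exact" if max(len(a), len(b)) <= 8 and _no_ties(a, b) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _no_ties(a: Sequence[float], b: Sequence[float]) -> bool:
    pooled = list(a) + list(b)
    return len(set(pooled)) == len(pooled)


def screen_matrix(
    values: pd.DataFrame,
    statuses: Mapping[str, SampleHemolysisStatus],
    a414: Mapping[str, float],
) -> list[HemolysisVerdict]:
    """Run the per-assay verdict over a samples x assays Ct matrix."""
    return [
        mirna_hemolysis_association(aid, values[aid].to_dict(), statuses, a414)
        for aid in values.columns
    ]


def verdicts_frame(verdicts: Sequence[HemolysisVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"assay_id": v.assay_id, "r2": v.r2, "p": v.p, "class": v.klass,
             "reason": v.reason}
            for v in verdicts
        ]
    )


def write_verdicts(verdicts: Sequence[HemolysisVerdict], path: str | Path) -> None:
    verdicts_frame(verdicts).to_csv(path, index=False)


def write_statuses(
    statuses: Mapping[str, SampleHemolysisStatus],
    absorbances: Mapping[str, tuple[float, float]],
    path: str | Path,
) -> None:
    rows = [
        {"sample_id": sid, "a414": absorbances[sid][0], "a375": absorbances[sid][1],
         "admitted": st.admitted, "class": st.klass}
        for sid, st in statuses.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
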