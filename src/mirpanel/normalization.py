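"""Endogenous-control selection and comparative-Ct normalization.

RT-qPCR panels of circulating miRNAs have no universally valid endogenous
control, so stable references are chosen from the data.  Stability is scored
with the model-based variance-decomposition approach of NormFinder
(Andersen-style): for each candidate gene, within-group technical/biological
variance and between-group expression bias are estimated from a two-way
gene x sample model fitted per group on the Ct (log) scale, and combined into
a single stability value (lower = more stable).  Candidate sets are restricted
to assays expressed in every sample and not flagged as hemolysis-affected.

Normalization uses the comparative-Ct convention: the normalized expression of
assay *a* in sample *s* is

    dCt*(s, a) = geometric mean of the control Cts of s  -  Ct(s, a)

so larger values mean more abundant.  Case-vs-control effect sizes are
reported as fold-changes ``FC = 2**(dCt*_case - median control dCt*)`` and as
symmetric fold-differences (``FD = FC`` if >= 1, else ``-1/FC``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hemolysis import AFFECTED, UNAFFECTED, HemolysisVerdict

#: geNorm-style pairwise-variation threshold below which an extra control
#: adds nothing
PAIRWISE_VARIATION_THRESHOLD = 0.15


# ---------------------------------------------------------------------------
# NormFinder stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """Stability values and components for a candidate set.

    ``rho`` is the per-candidate stability (lower = more stable);
    ``intra_var`` the estimated within-group variance per candidate and group;
    ``inter_diff`` the shrunken between-group bias per candidate and group.
    """

    rho: pd.Series
    intra_var: pd.DataFrame     # candidates x groups
    inter_diff: pd.DataFrame    # candidates x groups (shrunken d)
    diff_var: pd.DataFrame      # candidates x groups (sampling variance of d-hat)
    group_sizes: pd.Series
    best_pair: tuple[str, str]
    data: pd.DataFrame = field(repr=False)     # samples x candidates Ct
    groups: pd.Series = field(repr=False)

    @property
    def ranking(self) -> list[str]:
        return list(self.rho.sort_values(kind="stable").index)

    def combo_stability(self, candidates: Sequence[str]) -> float:
        """Stability of the average of several candidates.

        The averaged pseudo-gene has bias ``mean(d)`` and sampling variance
        ``sum(var)/m^2`` per group; the same |bias| + SE combination is used
        as for single genes.
        """
        c = list(candidates)
        m = len(c)
        d = self.inter_diff.loc[c].mean(axis=0)
        v = self.diff_var.loc[c].sum(axis=0) / m**2
        return float((d.abs() + np.sqrt(v)).mean())


def normfinder_stability(
    ct: pd.DataFrame, groups: Sequence[str] | pd.Series
) -> StabilityResult:
    """Model-based stability estimation on a samples x candidates Ct matrix.

    Per group g (n_g samples, k candidates), the two-way model
    ``Ct = gene effect + sample effect + noise`` is fitted by means; the
    per-gene residual mean squares are bias-corrected into within-group
    variances.  Between-group biases (doubly centered gene-by-group means)
    are shrunken toward zero by the estimated variance of true biases across
    genes, and the stability is the group-averaged ``|bias| + SE`` of the
    shrunken bias.  NaN input (unexpressed candidate) is rejected.
    """
    if ct.isna().any().any():
        bad = sorted(ct.columns[ct.isna().any()])
        raise ValueError(f"candidates with missing/ceiling Ct values: {bad}")
    groups = pd.Series(np.asarray(groups), index=ct.index)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("each group needs >= 2 samples")
    k = ct.shape[1]
    if k < 2:
        raise ValueError("need >= 2 candidate assays")

    gene_group_mean = pd.DataFrame(index=ct.columns, columns=levels, dtype=float)
    intra = pd.DataFrame(index=ct.columns, columns=levels, dtype=float)
    for g in levels:
        sub = ct.loc[groups == g]                       # n_g x k
        n_g = len(sub)
        gm = sub.mean(axis=0)                           # per gene
        sm = sub.mean(axis=1)                           # per sample
        tot = float(sub.to_numpy().mean())
        resid = sub.sub(gm, axis=1).sub(sm, axis=0) + tot
        s2 = (resid**2).sum(axis=0) / (n_g - 1)
        if k > 2:
            sigma2 = (s2 - s2.sum() / (k * (k - 1))) * k / (k - 2)
        else:
            sigma2 = s2
        intra[g] = sigma2.clip(lower=0.0)
        gene_group_mean[g] = gm

    # doubly centered between-group biases: sum to 0 over genes and groups
    d = gene_group_mean.sub(gene_group_mean.mean(axis=1), axis=0)
    d = d.sub(d.mean(axis=0), axis=1)

    n_per_group = pd.Series({g: float(sizes[g]) for g in levels})
    var_of_dhat = intra.div(n_per_group, axis=1)
    n_groups = len(levels)
    gamma2 = float((d**2).to_numpy().sum()) / ((n_groups - 1) * (k - 1)) - float(
        var_of_dhat.to_numpy().mean()
    )
    gamma2 = max(gamma2, 0.0)

    if gamma2 > 0:
        shrink = gamma2 / (gamma2 + var_of_dhat)
    else:
        shrink = var_of_dhat * 0.0
    d_tilde = d * shrink

    # stability: |shrunken bias| plus the (unshrunken) standard error of the
    # bias estimate; under a null bias structure this ranks by variance
    rho = (d_tilde.abs() + np.sqrt(var_of_dhat)).mean(axis=1)
    rho.name = "stability"

    result = StabilityResult(
        rho=rho,
        intra_var=intra,
        inter_diff=d_tilde,
        diff_var=var_of_dhat,
        group_sizes=n_per_group,
        best_pair=("", ""),
        data=ct,
        groups=groups,
    )
    result.best_pair = _best_pair(result)
    return result


def _best_pair(res: StabilityResult) -> tuple[str, str]:
    cands = list(res.rho.index)
    best, best_val = None, math.inf
    for i, a in enumerate(cands):
        for b in cands[i + 1:]:
            v = res.combo_stability([a, b])
            if v < best_val - 1e-15:
                best, best_val = (a, b), v
    return best  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# control selection
# ---------------------------------------------------------------------------

@dataclass
class ControlSet:
    assays: list[str]
    audit: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"controls": self.assays, "audit": self.audit}, indent=2,
                       default=str)
        )


def eligible_candidates(
    assays: Iterable[str],
    verdicts: Mapping[str, HemolysisVerdict],
    expressed_in_all: Mapping[str, bool],
    whitelist: Sequence[str] = (),
) -> tuple[list[str], dict[str, str]]:
    """Apply the control-candidacy rules; returns (eligible, rejection reasons).

    Hemolysis-affected assays are never eligible; indeterminate assays only
    if whitelisted; an assay must be expressed (below the Ct ceiling) in
    every sample.
    """
    eligible, reasons = [], {}
    for a in assays:
        if not expressed_in_all.get(a, False):
            reasons[a] = "not_expressed_in_all_samples"
            continue
        v = verdicts.get(a)
        klass = v.klass if v is not None else "indeterminate"
        if klass == AFFECTED:
            reasons[a] = "hemolysis_affected"
        elif klass != UNAFFECTED and a not in whitelist:
            reasons[a] = "hemolysis_indeterminate"
        else:
            eligible.append(a)
    return eligible, reasons


def prescreen_candidates(
    ct: pd.DataFrame, eligible: Sequence[str], max_candidates: int = 10
) -> list[str]:
    """Cap the stability-candidate list at the least-variable eligible assays.

    Variance-decomposition stability estimation is intended for short
    candidate lists (around 5-10 genes); with long lists a single strongly
    group-shifted assay inflates the between-group variance estimate and
    weakens the shrinkage of noisy candidates.  Pooled (group-blind) SD is a
    standard pre-screen that does not peek at the group structure.
    """
    eligible = list(eligible)
    if len(eligible) <= max_candidates:
        return eligible
    sd = ct[eligible].std(ddof=1)
    return list(sd.sort_values(kind="stable").index[:max_candidates])


def pairwise_variation(ct: pd.DataFrame, set_a: Sequence[str], set_b: Sequence[str]) -> float:
    """SD over samples of the difference between the two normalization
    factors (mean Ct of each control set; Ct is already a log-scale signal)."""
    nf_a = ct[list(set_a)].mean(axis=1)
    nf_b = ct[list(set_b)].mean(axis=1)
    diff = nf_a - nf_b
    return float(diff.std(ddof=1)) if len(diff) > 1 else 0.0


def select_controls(
    stability: StabilityResult,
    verdicts: Mapping[str, HemolysisVerdict],
    expressed_in_all: Mapping[str, bool],
    whitelist: Sequence[str] = (),
    v_threshold: float = PAIRWISE_VARIATION_THRESHOLD,
) -> ControlSet:
    """Pick >= 3 endogenous controls from a stability analysis.

    The selected trio is the best stable pair plus the candidate minimizing
    the trio's combined stability.  A fourth control (the next candidate in
    the stability ranking) is added only when it provides a real reduction in
    normalization-factor variability: the pairwise-variation statistic of the
    trio (V between the 2- and 3-control normalization factors) must be at or
    above ``v_threshold`` while adding the fourth brings V(3, 4) below it.
    A fourth that leaves the variability where it was is unnecessary.
    """
    eligible, reasons = eligible_candidates(
        stability.rho.index, verdicts, expressed_in_all, whitelist
    )
    if len(eligible) < 3:
        raise ValueError(
            "fewer than 3 eligible control candidates; exclusions: "
            + json.dumps(reasons)
        )
    audit: dict = {
        "candidates_considered": list(stability.rho.index),
        "rejected": reasons,
        "eligible": list(eligible),
        "stability": {a: float(stability.rho[a]) for a in eligible},
        "whitelist": list(whitelist),
    }
    if len(eligible) < 5:
        audit["warning"] = "fewer than 5 eligible candidates; stability estimates weak"

    sub = _restrict(stability, eligible)
    pair = list(sub.best_pair)
    rest = [a for a in eligible if a not in pair]
    third = min(rest, key=lambda c: sub.combo_stability(pair + [c]))
    trio = pair + [third]
    audit["best_pair"] = pair
    audit["trio"] = list(trio)
    audit["trio_stability"] = sub.combo_stability(trio)

    selected = list(trio)
    remaining = [a for a in sub.ranking if a not in trio]
    v23 = pairwise_variation(stability.data, pair, trio)
    audit["pairwise_variation_2_3"] = v23
    audit["v_threshold"] = v_threshold
    if remaining:
        fourth = remaining[0]  # next most stable candidate
        v34 = pairwise_variation(stability.data, trio, trio + [fourth])
        audit["fourth_candidate"] = fourth
        audit["pairwise_variation_3_4"] = v34
        if v23 >= v_threshold and v34 < v_threshold:
            selected.append(fourth)
            audit["fourth_added"] = True
        else:
            audit["fourth_added"] = False
    return ControlSet(assays=selected, audit=audit)


def _restrict(res: StabilityResult, assays: Sequence[str]) -> StabilityResult:
    keep = list(assays)
    out = StabilityResult(
        rho=res.rho.loc[keep],
        intra_var=res.intra_var.loc[keep],
        inter_diff=res.inter_diff.loc[keep],
        diff_var=res.diff_var.loc[keep],
        group_sizes=res.group_sizes,
        best_pair=("", ""),
        data=res.data[keep],
        groups=res.groups,
    )
    out.best_pair = _best_pair(out)
    return out


# ---------------------------------------------------------------------------
# normalization and fold arithmetic
# ---------------------------------------------------------------------------

@dataclass
class NormalizedMatrix:
    """Samples x assays of normalized expression dCt* (larger = more abundant)."""

    values: pd.DataFrame
    controls: list[str]

    def non_control_values(self) -> pd.DataFrame:
        """Expression of the non-control assays (controls self-normalize and
        are excluded from downstream testing and modelling)."""
        keep = [a for a in self.values.columns if a not in self.controls]
        return self.values[keep]


def normalize(
    ct: pd.DataFrame,
    controls: Sequence[str],
    ceiling: float | None = None,
) -> NormalizedMatrix:
    """Comparative-Ct normalization against the geometric mean of the controls.

    ``dCt*(s, a) = geomean_{c in controls} Ct(s, c) - Ct(s, a)``, computed on
    the full combined sample set in one pass.  The geometric mean is taken of
    the Ct values themselves.  Any control at/above the ceiling or missing is
    an error — the control-set invariant requires expression in all samples.
    """
    controls = list(controls)
    missing = [c for c in controls if c not in ct.columns]
    if missing:
        raise ValueError(f"controls absent from matrix: {missing}")
    sub = ct[controls]
    bad = sub.isna()
    if ceiling is not None:
        bad = bad | sub.ge(ceiling)
    if bad.any().any():
        rows = sorted(sub.index[bad.any(axis=1)])
        raise ValueError(
            f"control assays unexpressed (missing or at the ceiling) in samples {rows}"
        )
    geo = np.exp(np.log(sub).mean(axis=1))
    values = (-ct).add(geo, axis=0)
    return NormalizedMatrix(values=values, controls=controls)


def fold_change(case_delta: np.ndarray | pd.Series, control_median: float) -> np.ndarray:
    """Per-case fold-change ``2**(dCt*_case - median control dCt*)``."""
    return np.power(2.0, np.asarray(case_delta, dtype=float) - control_median)


def fold_difference(fc: float) -> float:
    """Symmetric fold-difference: FC when >= 1, else -1/FC.  |FD| >= 1 always."""
    fc = float(fc)
    if fc <= 0:
        raise ValueError("fold-change must be positive")
    return fc if fc >= 1.0 else -1.0 / fc


def median_fold_difference(
    case_delta: np.ndarray | pd.Series, control_delta: np.ndarray | pd.Series
) -> float:
    """Median fold-change over case samples, reported as a fold-difference."""
    ctrl_median = float(np.median(np.asarray(control_delta, dtype=float)))
    fc = float(np.median(fold_change(case_delta, ctrl_median)))
    return fold_difference(fc)
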