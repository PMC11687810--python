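"""Survival primitives: Kaplan-Meier, log-rank, optimal cutpoints, Cox.

Endpoints are overall survival and disease-free interval in days, plus
fixed-horizon variants (6-month / 1-year / 2-year) obtained by administrative
censoring at 183 / 365 / 730 days.  Expression markers are dichotomized at
the maximally selected log-rank cutpoint with a minimum group proportion
(minprop, default 0.2); "high" always refers to the abundance scale of the
normalized expression, so "marker-high implies shorter survival" reads the
way clinicians expect.

The optimal-cutpoint p-values reported downstream are the ordinary log-rank
p of the dichotomized groups; they inherit the optimism of data-driven
cutpoints (no Lausen-Schumacher correction is applied).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: fixed-horizon endpoints, days
HORIZONS = {"6m": 183, "1y": 365, "2y": 730}

DEFAULT_MINPROP = 0.2


# ---------------------------------------------------------------------------
# endpoints
# ---------------------------------------------------------------------------

def apply_horizon(
    time: np.ndarray, event: np.ndarray, horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring at a fixed horizon (days).

    Events after the horizon become censored at the horizon, so a sample
    that is an event at 183 days is also an event at 365 and 730 days.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    new_time = np.minimum(time, horizon)
    new_event = np.where(time <= horizon, event, 0)
    return new_time, new_event


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMEstimate:
    """Product-limit estimate: right-continuous step function S(t)."""

    event_times: np.ndarray      # distinct times with >= 1 event
    survival: np.ndarray         # S at those times
    n_samples: int
    n_events: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """Smallest time with S(t) <= 0.5; NaN when S never reaches 0.5."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if len(below) else math.nan


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMEstimate:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("need >= 1 sample")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    s = 1.0
    ts, ss = [], []
    for t in np.unique(time[event == 1]):
        at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / at_risk
        ts.append(t)
        ss.append(s)
    return KMEstimate(
        event_times=np.array(ts),
        survival=np.array(ss),
        n_samples=len(time),
        n_events=int(event.sum()),
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_oe(
    time_a, event_a, time_b, event_b
) -> tuple[float, float, float]:
    """(O_A - E_A, V, O_A) of the two-group log-rank test."""
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a, dtype=int)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b, dtype=int)
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    obs = 0.0
    for t in times:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        n = na + nb
        if na == 0 or nb == 0:
            continue
        da = np.sum((ta == t) & (ea == 1))
        db = np.sum((tb == t) & (eb == 1))
        d = da + db
        e = d * na / n
        o_minus_e += da - e
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
        obs += da
    return float(o_minus_e), float(var), float(obs)


def logrank_test(
    time_a, event_a, time_b, event_b
) -> tuple[float, float]:
    """Two-group log-rank test: (chi2, p) with 1 df.

    When the groups never overlap in risk sets the variance is zero and the
    result is NaN with a warning.
    """
    oe, var, _ = _logrank_oe(time_a, event_a, time_b, event_b)
    if var <= 0:
        if oe == 0:
            return 0.0, 1.0
        logger.warning("log-rank: no at-risk overlap between groups; p undefined")
        return math.nan, math.nan
    chi2 = oe * oe / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_z(time_a, event_a, time_b, event_b) -> float:
    """Standardized log-rank statistic (O_A - E_A)/sqrt(V); NaN if V = 0."""
    oe, var, _ = _logrank_oe(time_a, event_a, time_b, event_b)
    return oe / math.sqrt(var) if var > 0 else math.nan


def pairwise_logrank(
    groups: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """All pairwise log-rank tests with Bonferroni adjustment.

    Returns a tidy frame with columns group_a, group_b, chi2, raw_p,
    adjusted_p where ``adjusted_p = min(1, raw_p * n_pairs)``.
    """
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        chi2, p = logrank_test(*groups[a], *groups[b])
        rows.append(
            {"group_a": a, "group_b": b, "chi2": chi2, "raw_p": p,
             "adjusted_p": min(1.0, p * m) if not math.isnan(p) else math.nan}
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "chi2", "raw_p", "adjusted_p"])


# ---------------------------------------------------------------------------
# maximally selected cutpoint
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    assay_id: str
    cutpoint: float
    statistic: float             # standardized log-rank statistic at the cutpoint
    labels: pd.Series            # "high"/"low" per sample (abundance scale)
    minprop: float


def candidate_cutpoints(expression: np.ndarray, minprop: float) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values whose split
    leaves at least ``floor(minprop * n)`` (>= 1) samples on each side."""
    x = np.asarray(expression, dtype=float)
    n = len(x)
    min_count = max(1, int(math.floor(minprop * n)))
    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    ok = []
    for c in mids:
        n_low = int(np.sum(x <= c))
        if n_low >= min_count and (n - n_low) >= min_count:
            ok.append(c)
    return np.array(ok)


def max_selected_cutpoint(
    expression: pd.Series | np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    minprop: float = DEFAULT_MINPROP,
    assay_id: str = "",
) -> CutpointResult:
    """Optimal dichotomization by the maximally selected log-rank statistic.

    Candidate cutpoints never split tied expression values; the returned
    cutpoint maximizes |standardized log-rank statistic| between the induced
    low (expression <= cut) and high groups, ties resolved toward the
    smallest cutpoint.
    """
    if isinstance(expression, pd.Series):
        index = expression.index
        x = expression.to_numpy(dtype=float)
    else:
        x = np.asarray(expression, dtype=float)
        index = pd.RangeIndex(len(x))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(x)
    if n < math.ceil(1.0 / minprop):
        raise ValueError(f"need >= {math.ceil(1 / minprop)} samples at minprop={minprop}")
    if np.ptp(x) == 0:
        raise ValueError("no admissible cutpoint: constant expression")
    cands = candidate_cutpoints(x, minprop)
    if len(cands) == 0:
        raise ValueError("no admissible cutpoint under the minprop constraint")
    best_c, best_z = None, -1.0
    best_signed = math.nan
    for c in cands:
        low = x <= c
        z = logrank_z(time[low], event[low], time[~low], event[~low])
        if math.isnan(z):
            continue
        if abs(z) > best_z + 1e-12:
            best_c, best_z, best_signed = float(c), abs(z), z
    if best_c is None:
        raise ValueError("log-rank statistic undefined at every admissible cutpoint")
    labels = pd.Series(np.where(x > best_c, "high", "low"), index=index)
    return CutpointResult(
        assay_id=assay_id, cutpoint=best_c, statistic=best_signed,
        labels=labels, minprop=minprop,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (univariate, Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    reference: str | None = None
    level: str | None = None
    n: int = 0
    n_events: int = 0
    flags: list[str] = field(default_factory=list)


class CoxSeparationWarning(UserWarning):
    pass


def _efron_loglik(beta, x, time, event):
    """Efron partial log-likelihood, gradient and information for covariates x
    (n x p), samples sorted by ascending time."""
    n, p = x.shape
    theta = np.exp(x @ beta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    # iterate distinct event times
    event_times = np.unique(time[event == 1])
    for t in event_times:
        risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        th_r = theta[risk]
        x_r = x[risk]
        th_d = theta[dead]
        x_d = x[dead]
        s0_r = th_r.sum()
        s1_r = th_r @ x_r
        s2_r = (th_r[:, None] * x_r).T @ x_r
        s0_d = th_d.sum()
        s1_d = th_d @ x_d
        s2_d = (th_d[:, None] * x_d).T @ x_d
        ll += float(np.log(theta[dead]).sum())
        for l in range(d):
            f = l / d
            phi = s0_r - f * s0_d
            num1 = s1_r - f * s1_d
            num2 = s2_r - f * s2_d
            ll -= math.log(phi)
            grad -= num1 / phi
            info += num2 / phi - np.outer(num1, num1) / phi**2
        grad += x_d.sum(axis=0)
    return ll, grad, info


def _fit_cox(x: np.ndarray, time: np.ndarray, event: np.ndarray,
             max_iter: int = 50, tol: float = 1e-9):
    """Damped Newton maximization of the Efron partial likelihood."""
    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    p = x.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _efron_loglik(beta, x, time, event)
    flags: list[str] = []
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        # step halving
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _efron_loglik(cand, x, time, event)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(grad)) < tol or np.max(np.abs(factor * step)) < tol:
            break
    if np.max(np.abs(beta)) > 15:
        flags.append("monotone_likelihood")
        warnings.warn(
            "Cox fit diverging (perfect separation); CI unbounded",
            CoxSeparationWarning,
        )
    return beta, info, flags


def cox_univariate(
    covariate: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    name: str = "x",
) -> CoxResult:
    """Univariate Cox regression of a numeric covariate.

    HR = exp(beta) per unit of the covariate; 95% CI from the observed
    information.  Perfect separation is flagged and the CI reported as
    unbounded.
    """
    x = np.asarray(covariate, dtype=float).reshape(-1, 1)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if event.sum() == 0:
        raise ValueError("need >= 1 event")
    beta, info, flags = _fit_cox(x, time, event)
    b = float(beta[0])
    with np.errstate(invalid="ignore"):
        se = float(np.sqrt(np.linalg.inv(info)[0, 0])) if np.all(np.isfinite(info)) else math.nan
    if "monotone_likelihood" in flags:
        return CoxResult(
            covariate=name, hr=math.exp(b), ci_low=0.0, ci_high=math.inf,
            p=math.nan, beta=b, se=math.inf, n=len(time),
            n_events=int(event.sum()), flags=flags,
        )
    z = b / se
    return CoxResult(
        covariate=name,
        hr=math.exp(b),
        ci_low=math.exp(b - 1.96 * se),
        ci_high=math.exp(b + 1.96 * se),
        p=float(2 * stats.norm.sf(abs(z))),
        beta=b,
        se=se,
        n=len(time),
        n_events=int(event.sum()),
        flags=flags,
    )


def cox_categorical(
    values: Sequence[str],
    time: Sequence[float],
    event: Sequence[int],
    reference: str,
    name: str = "x",
) -> list[CoxResult]:
    """Cox regression of a categorical covariate against a reference level.

    Non-reference levels are dummy-coded into one joint fit; one
    :class:`CoxResult` per level is returned.  Levels with a single sample
    are inestimable and reported with NaN statistics.
    """
    vals = pd.Series([str(v) for v in values])
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    levels = sorted(vals.unique())
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent")
    counts = vals.value_counts()
    estimable = [l for l in levels if l != reference and counts[l] > 1]
    rare = [l for l in levels if l != reference and counts[l] <= 1]
    results = []
    if estimable:
        x = np.column_stack([(vals == l).to_numpy(dtype=float) for l in estimable])
        beta, info, flags = _fit_cox(x, time, event)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full_like(info, math.nan)
        for j, l in enumerate(estimable):
            b = float(beta[j])
            se = float(math.sqrt(max(cov[j, j], 0.0))) if np.isfinite(cov[j, j]) else math.nan
            if "monotone_likelihood" in flags or not np.isfinite(se) or se == 0:
                results.append(CoxResult(
                    covariate=name, hr=math.exp(b), ci_low=0.0, ci_high=math.inf,
                    p=math.nan, beta=b, se=math.inf, reference=reference, level=l,
                    n=len(time), n_events=int(event.sum()),
                    flags=flags + ["unstable_se"] if not np.isfinite(se) else flags,
                ))
            else:
                z = b / se
                results.append(CoxResult(
                    covariate=name, hr=math.exp(b),
                    ci_low=math.exp(b - 1.96 * se), ci_high=math.exp(b + 1.96 * se),
                    p=float(2 * stats.norm.sf(abs(z))), beta=b, se=se,
                    reference=reference, level=l,
                    n=len(time), n_events=int(event.sum()), flags=flags,
                ))
    for l in rare:
        results.append(CoxResult(
            covariate=name, hr=math.nan, ci_low=math.nan, ci_high=math.nan,
            p=math.nan, beta=math.nan, se=math.nan, reference=reference, level=l,
            n=len(time), n_events=int(event.sum()), flags=["inestimable_single_sample"],
        ))
    return results


def cox_all_references(
    values: Sequence[str],
    time: Sequence[float],
    event: Sequence[int],
    name: str = "x",
) -> list[CoxResult]:
    """Repeat the categorical fit with every level serving as reference."""
    vals = pd.Series([str(v) for v in values])
    out: list[CoxResult] = []
    for ref in sorted(vals.unique()):
        if (vals == ref).sum() <= 1:
            continue  # a single-sample reference supports no contrast
        out.extend(cox_categorical(values, time, event, reference=ref, name=name))
    return out
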