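"""End-to-end orchestration of the plasma miRNA panel analysis.

Stages (each independently re-runnable; each consumes the previous stage's
CSV/JSON artifacts from a single run directory):

    simulate  -> fixture/            synthetic plates + metadata + truth
    qc        -> qc/                 calibrated, ceiled, filtered Ct matrix
    hemolysis -> hemolysis/          sample statuses + per-assay verdicts
    normalize -> normalize/          control selection + normalized matrix
    de        -> de/                 per-cohort differential expression
    survival  -> survival/           per-miRNA cutpoints + clinical Cox
    trees     -> trees/              diagnostic + prognostic tree models
    report    -> report.md           human-readable summary

Every stage is deterministic given the run config and seed; re-running a
stage on unchanged inputs reproduces its outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .plates import (
    DEFAULT_CEILING, QcReport, SampleRecord, apply_ceiling, assay_prevalence_filter,
    ipc_correct, read_plates, read_samples, sample_detection_filter, samples_frame,
    spike_in_filter,
)
from .hemolysis import (
    classify_samples, screen_matrix, verdicts_frame, write_statuses, write_verdicts,
    HemolysisVerdict, UNAFFECTED,
)
from .normalization import (
    NormalizedMatrix, eligible_candidates, normalize, normfinder_stability,
    prescreen_candidates, select_controls,
)
from .diffexpr import de_frame, de_table
from .survival import (
    HORIZONS, apply_horizon, cox_all_references, cox_univariate, km_estimate,
    logrank_test, max_selected_cutpoint, DEFAULT_MINPROP,
)
from .trees import (
    TreeParams, Tree, assign_groups, compare_groups, crossval_prune,
    evaluate_classifier, grow_classification_tree, grow_survival_tree,
)
from .synthetic import CohortConfig, generate_cohort, write_fixture

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "hemolysis", "normalize", "de", "survival", "trees", "report"]


@dataclass
class RunConfig:
    """All pipeline thresholds, surfaced with their conventional defaults."""

    ceiling: float = DEFAULT_CEILING
    minprop: float = DEFAULT_MINPROP
    bh_alpha: float = 0.05
    horizons: dict[str, int] = field(default_factory=lambda: dict(HORIZONS))
    control_whitelist: list[str] = field(
        default_factory=lambda: ["hsa-let-7c-5p", "cfa-miR-140"]
    )
    #: stability estimation works best on a short candidate list (5-10 genes);
    #: eligible assays are pre-screened by pooled variance down to this many
    normfinder_max_candidates: int = 10
    v_threshold: float = 0.15
    tree_min_split: int = 20
    tree_min_leaf: int = 7
    tree_cp: float = 0.01
    tree_k_folds: int = 10
    control_holdout: float = 0.2     # fraction of controls withheld for the test set
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        if not (0 < self.minprop <= 0.5):
            raise ValueError(f"minprop must be in (0, 0.5], got {self.minprop}")
        if not (0 < self.bh_alpha < 1):
            raise ValueError("bh_alpha must be in (0, 1)")
        if self.ceiling <= 0:
            raise ValueError("ceiling must be positive")
        if not (0 <= self.control_holdout < 1):
            raise ValueError("control_holdout must be in [0, 1)")
        for k, v in self.horizons.items():
            if v <= 0:
                raise ValueError(f"horizon {k} must be positive")
        self.cohort.validate()

    def tree_params(self) -> TreeParams:
        return TreeParams(
            min_split=self.tree_min_split, min_leaf=self.tree_min_leaf,
            cp=self.tree_cp, k_folds=self.tree_k_folds,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cohort = data.pop("cohort", None)
        cfg = cls(**data)
        if cohort is not None:
            cfg.cohort = CohortConfig(**cohort)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


class MissingStageError(FileNotFoundError):
    def __init__(self, artifact: Path, stage: str):
        super().__init__(
            f"required artifact {artifact} is missing; run the '{stage}' stage first"
        )


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingStageError(path, stage)
    return path


def _write_provenance(run_dir: Path, config: RunConfig, stage: str) -> None:
    prov = run_dir / "provenance.json"
    entry = {"stage": stage, "config_digest": config.digest(), "seed": config.seed,
             "version": __version__}
    existing = json.loads(prov.read_text()) if prov.exists() else []
    existing = [e for e in existing if e["stage"] != stage]
    existing.append(entry)
    prov.write_text(json.dumps(sorted(existing, key=lambda e: STAGES.index(e["stage"])),
                               indent=2))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, run_dir: Path) -> None:
    cohort_cfg = config.cohort
    plates, samples, truth = generate_cohort(cohort_cfg)
    fixture = run_dir / "fixture"
    write_fixture(plates, samples, fixture, truth=truth)
    cohort_cfg.to_yaml(fixture / "cohort_config.yaml")
    _write_provenance(run_dir, config, "simulate")


def stage_qc(config: RunConfig, run_dir: Path) -> None:
    fixture = run_dir / "fixture"
    _require(fixture / "samples.csv", "simulate")
    plate_paths = sorted(fixture.glob("plate_*.csv"))
    plates = read_plates(plate_paths)
    samples = read_samples(fixture / "samples.csv")

    matrix, report = ipc_correct(plates)
    matrix = apply_ceiling(matrix, config.ceiling)

    spike_pass = spike_in_filter(samples, report)
    detect_pass = sample_detection_filter(matrix, report)
    kept_assays, _ = assay_prevalence_filter(matrix, report)

    keep_samples = [
        s.sample_id for s in samples
        if spike_pass.get(s.sample_id, False) and detect_pass.get(s.sample_id, True)
    ]
    values = matrix.values.loc[keep_samples, kept_assays]

    out = run_dir / "qc"
    out.mkdir(parents=True, exist_ok=True)
    values.to_csv(out / "matrix.csv", float_format="%.6f")
    report.to_json(out / "report.json")
    (out / "report.log").write_text(report.summary() + "\n")
    _write_provenance(run_dir, config, "qc")


def _load_matrix(run_dir: Path) -> pd.DataFrame:
    path = _require(run_dir / "qc" / "matrix.csv", "qc")
    return pd.read_csv(path, index_col=0)


def _load_samples(run_dir: Path) -> list[SampleRecord]:
    path = _require(run_dir / "fixture" / "samples.csv", "simulate")
    return read_samples(path)


def stage_hemolysis(config: RunConfig, run_dir: Path) -> None:
    values = _load_matrix(run_dir)
    samples = _load_samples(run_dir)
    absorb = {
        s.sample_id: (s.a414, s.a375)
        for s in samples
        if s.sample_id in values.index and s.a414 is not None and s.a375 is not None
    }
    statuses = classify_samples(absorb)
    a414 = {sid: ab[0] for sid, ab in absorb.items()}
    verdicts = screen_matrix(values, statuses, a414)

    out = run_dir / "hemolysis"
    out.mkdir(parents=True, exist_ok=True)
    write_statuses(statuses, absorb, out / "statuses.csv")
    write_verdicts(verdicts, out / "verdicts.csv")
    _write_provenance(run_dir, config, "hemolysis")


def _load_verdicts(run_dir: Path) -> dict[str, HemolysisVerdict]:
    path = _require(run_dir / "hemolysis" / "verdicts.csv", "hemolysis")
    df = pd.read_csv(path)
    return {
        r.assay_id: HemolysisVerdict(
            assay_id=r.assay_id, r2=r.r2, p=r.p, klass=r["class"],
            reason=r.reason if isinstance(r.reason, str) else "",
        )
        for _, r in df.iterrows()
    }


def _admitted_samples(run_dir: Path) -> list[str]:
    path = _require(run_dir / "hemolysis" / "statuses.csv", "hemolysis")
    df = pd.read_csv(path)
    return list(df.loc[df["admitted"], "sample_id"])


def stage_normalize(config: RunConfig, run_dir: Path) -> None:
    values = _load_matrix(run_dir)
    samples = {s.sample_id: s for s in _load_samples(run_dir)}
    verdicts = _load_verdicts(run_dir)
    admitted = [s for s in _admitted_samples(run_dir) if s in values.index]
    values = values.loc[admitted]

    expressed_in_all = values.lt(config.ceiling).all(axis=0).to_dict()
    eligible, _ = eligible_candidates(
        values.columns, verdicts, expressed_in_all, config.control_whitelist
    )
    if len(eligible) < 3:
        raise ValueError("fewer than 3 eligible endogenous-control candidates")
    eligible = prescreen_candidates(values, eligible, config.normfinder_max_candidates)
    groups = [samples[sid].group for sid in values.index]
    stability = normfinder_stability(values[eligible], groups)
    controls = select_controls(
        stability, verdicts, expressed_in_all,
        whitelist=config.control_whitelist, v_threshold=config.v_threshold,
    )
    normalized = normalize(values, controls.assays, ceiling=config.ceiling)

    out = run_dir / "normalize"
    out.mkdir(parents=True, exist_ok=True)
    normalized.values.to_csv(out / "normalized.csv", float_format="%.6f")
    stab = stability.rho.sort_values().rename("stability").to_frame()
    stab["rank"] = range(1, len(stab) + 1)
    stab.to_csv(out / "stability.csv", index_label="assay_id", float_format="%.6g")
    controls.to_json(out / "controls.json")
    _write_provenance(run_dir, config, "normalize")


def _load_normalized(run_dir: Path) -> NormalizedMatrix:
    path = _require(run_dir / "normalize" / "normalized.csv", "normalize")
    controls = json.loads(
        _require(run_dir / "normalize" / "controls.json", "normalize").read_text()
    )["controls"]
    return NormalizedMatrix(values=pd.read_csv(path, index_col=0), controls=controls)


def stage_de(config: RunConfig, run_dir: Path) -> None:
    normalized = _load_normalized(run_dir)
    samples = _load_samples(run_dir)
    groups = {s.sample_id: s.group for s in samples}
    cohorts = {s.sample_id: s.cohort for s in samples}
    out = run_dir / "de"
    out.mkdir(parents=True, exist_ok=True)
    for cohort in config.cohort.cohort_names:
        results = de_table(normalized, groups, cohorts, cohort, alpha=config.bh_alpha)
        de_frame(results).to_csv(out / f"de_{cohort}.csv", index=False,
                                 float_format="%.6g")
    _write_provenance(run_dir, config, "de")


def _endpoint_arrays(
    samples: Sequence[SampleRecord], ids: Sequence[str], endpoint: str,
    horizons: dict[str, int],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    by_id = {s.sample_id: s for s in samples}
    base = "os" if endpoint != "dfi" else "dfi"
    rows = [
        sid for sid in ids
        if getattr(by_id[sid], f"{base}_time") is not None
        and getattr(by_id[sid], f"{base}_event") is not None
    ]
    time = np.array([getattr(by_id[sid], f"{base}_time") for sid in rows])
    event = np.array([getattr(by_id[sid], f"{base}_event") for sid in rows])
    if endpoint in horizons:
        time, event = apply_horizon(time, event, horizons[endpoint])
    return time, event, rows


def stage_survival(config: RunConfig, run_dir: Path) -> None:
    normalized = _load_normalized(run_dir)
    samples = _load_samples(run_dir)
    values = normalized.non_control_values()
    case_ids = [s.sample_id for s in samples
                if s.group == "case" and s.sample_id in values.index]
    out = run_dir / "survival"
    out.mkdir(parents=True, exist_ok=True)

    endpoints = ["os", "dfi"] + list(config.horizons)
    cohort_of = {s.sample_id: s.cohort for s in samples}
    for endpoint in endpoints:
        rows = []
        for cohort in config.cohort.cohort_names + ["pooled"]:
            ids = case_ids if cohort == "pooled" else [
                sid for sid in case_ids if cohort_of[sid] == cohort
            ]
            time, event, kept = _endpoint_arrays(samples, ids, endpoint, config.horizons)
            if len(kept) < math.ceil(1 / config.minprop) or event.sum() == 0:
                continue
            for assay in values.columns:
                expr = values.loc[kept, assay]
                if expr.nunique() < 2:
                    continue
                try:
                    cut = max_selected_cutpoint(
                        expr, time, event, minprop=config.minprop, assay_id=assay
                    )
                except ValueError:
                    continue
                high = cut.labels == "high"
                chi2, p = logrank_test(
                    time[high.to_numpy()], event[high.to_numpy()],
                    time[~high.to_numpy()], event[~high.to_numpy()],
                )
                km_high = km_estimate(time[high.to_numpy()], event[high.to_numpy()])
                km_low = km_estimate(time[~high.to_numpy()], event[~high.to_numpy()])
                rows.append(
                    {"cohort": cohort, "assay_id": assay, "cutpoint": cut.cutpoint,
                     "statistic": cut.statistic, "n_high": int(high.sum()),
                     "n_low": int((~high).sum()), "chi2": chi2, "logrank_p": p,
                     "median_high": km_high.median, "median_low": km_low.median}
                )
        pd.DataFrame(rows).to_csv(out / f"cutpoints_{endpoint}.csv", index=False,
                                  float_format="%.6g")

    # univariate Cox of clinical covariates (case samples with clinical data)
    cox_rows = []
    for endpoint in ("os", "dfi"):
        time, event, kept = _endpoint_arrays(samples, case_ids, endpoint, {})
        by_id = {s.sample_id: s for s in samples}
        for cov in ("age", "weight"):
            vals = np.array(
                [getattr(by_id[sid], cov) if getattr(by_id[sid], cov) is not None
                 else np.nan for sid in kept]
            )
            ok = ~np.isnan(vals)
            if ok.sum() < 3 or np.ptp(vals[ok]) == 0 or event[ok].sum() == 0:
                continue
            res = cox_univariate(vals[ok], time[ok], event[ok], name=cov)
            cox_rows.append({"endpoint": endpoint, **_cox_row(res)})
        for cov in ("sex", "tumour_location", "alp_status"):
            vals = [getattr(by_id[sid], cov) for sid in kept]
            ok = np.array([v is not None for v in vals])
            if ok.sum() < 3 or event[ok].sum() == 0:
                continue
            sub = [v for v in vals if v is not None]
            if len(set(sub)) < 2:
                continue
            for res in cox_all_references(sub, time[ok], event[ok], name=cov):
                cox_rows.append({"endpoint": endpoint, **_cox_row(res)})
    pd.DataFrame(cox_rows).to_csv(out / "cox_clinical.csv", index=False,
                                  float_format="%.6g")
    _write_provenance(run_dir, config, "survival")


def _cox_row(res) -> dict:
    return {
        "covariate": res.covariate, "level": res.level, "reference": res.reference,
        "hr": res.hr, "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
        "n": res.n, "events": res.n_events, "flags": ";".join(res.flags),
    }


def diagnostic_split(
    samples: Sequence[SampleRecord], available: Sequence[str],
    train_cohorts: Sequence[str], test_cohorts: Sequence[str],
    holdout: float, seed: int,
) -> tuple[list[str], list[str]]:
    """Train = the training cohorts' cases plus (1 - holdout) of the controls;
    test = the test cohorts' cases plus the held-out controls."""
    avail = set(available)
    controls = sorted(s.sample_id for s in samples
                      if s.group == "control" and s.sample_id in avail)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(controls))
    n_test = int(round(holdout * len(controls)))
    test_ctrl = {controls[i] for i in perm[:n_test]}
    train = [s.sample_id for s in samples
             if s.sample_id in avail and (
                 (s.group == "case" and s.cohort in train_cohorts)
                 or (s.group == "control" and s.sample_id not in test_ctrl))]
    test = [s.sample_id for s in samples
            if s.sample_id in avail and (
                (s.group == "case" and s.cohort in test_cohorts)
                or s.sample_id in test_ctrl)]
    return train, test


def stage_trees(config: RunConfig, run_dir: Path) -> None:
    normalized = _load_normalized(run_dir)
    samples = _load_samples(run_dir)
    verdicts = _load_verdicts(run_dir)
    values = normalized.non_control_values()
    params = config.tree_params()
    out = run_dir / "trees"
    out.mkdir(parents=True, exist_ok=True)
    by_id = {s.sample_id: s for s in samples}

    # diagnostic tree: first cohorts train, last cohort tests
    names = config.cohort.cohort_names
    train_ids, test_ids = diagnostic_split(
        samples, values.index, train_cohorts=names[:-1], test_cohorts=names[-1:],
        holdout=config.control_holdout, seed=config.seed,
    )
    labels_tr = [by_id[s].group for s in train_ids]
    labels_te = [by_id[s].group for s in test_ids]
    tree = grow_classification_tree(values.loc[train_ids], labels_tr, params)
    pruned, trace = crossval_prune(tree, values.loc[train_ids], labels=labels_tr,
                                   seed=config.seed)
    pruned.to_json(out / "diagnostic_tree.json")
    (out / "diagnostic_tree.txt").write_text(pruned.root.render() + "\n")
    trace.frame().to_csv(out / "diagnostic_prune_trace.csv", index=False,
                         float_format="%.6g")
    metrics = {
        "train": evaluate_classifier(pruned, values.loc[train_ids], labels_tr),
        "test": evaluate_classifier(pruned, values.loc[test_ids], labels_te),
    }
    pd.DataFrame(
        [{"split": k, **asdict(m)} for k, m in metrics.items()]
    ).to_csv(out / "diagnostic_metrics.csv", index=False, float_format="%.6g")

    # prognostic survival trees: pooled cases, hemolysis-unaffected markers only
    safe = [a for a in values.columns
            if a in verdicts and verdicts[a].klass == UNAFFECTED]
    case_ids = [s.sample_id for s in samples
                if s.group == "case" and s.sample_id in values.index]
    endpoints = ["os", "dfi"] + list(config.horizons)
    for endpoint in endpoints:
        time, event, kept = _endpoint_arrays(samples, case_ids, endpoint,
                                             config.horizons)
        if event.sum() == 0 or not safe:
            continue
        X = values.loc[kept, safe]
        stree = grow_survival_tree(X, time, event, params)
        spruned, strace = crossval_prune(stree, X, time=time, event=event,
                                         seed=config.seed)
        spruned.to_json(out / f"survival_tree_{endpoint}.json")
        (out / f"survival_tree_{endpoint}.txt").write_text(
            spruned.root.render() + "\n")
        strace.frame().to_csv(out / f"survival_prune_trace_{endpoint}.csv",
                              index=False, float_format="%.6g")
        groups = assign_groups(spruned, X)
        groups.rename("group").to_csv(out / f"groups_{endpoint}.csv",
                                      index_label="sample_id")
        comp = compare_groups(groups, time, event, use_cox=True)
        comp["groups"].to_csv(out / f"group_summary_{endpoint}.csv", index=False,
                              float_format="%.6g")
        comp["pairwise"].to_csv(out / f"group_pairwise_{endpoint}.csv", index=False,
                                float_format="%.6g")
    _write_provenance(run_dir, config, "trees")


def stage_report(config: RunConfig, run_dir: Path) -> None:
    _require(run_dir / "de", "de")
    lines = ["# Panel analysis report", ""]
    prov = run_dir / "provenance.json"
    if prov.exists():
        entries = json.loads(prov.read_text())
        lines += [f"config digest: `{entries[0]['config_digest']}`; "
                  f"seed {config.seed}; mirpanel {__version__}", ""]
    qc_path = run_dir / "qc" / "report.json"
    if qc_path.exists():
        qc = json.loads(qc_path.read_text())
        lines += ["## Quality control", "",
                  f"- excluded samples: {len(qc['excluded_samples'])}",
                  f"- excluded assays: {len(qc['excluded_assays'])}", ""]
    ctrl_path = run_dir / "normalize" / "controls.json"
    if ctrl_path.exists():
        ctrl = json.loads(ctrl_path.read_text())
        lines += ["## Endogenous controls", "",
                  f"- selected: {', '.join(ctrl['controls'])}", ""]
    lines += ["## Differential expression", ""]
    for cohort in config.cohort.cohort_names:
        path = run_dir / "de" / f"de_{cohort}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path)
        sig = df[df["fdr_p"] < config.bh_alpha]
        lines.append(f"### {cohort}: {len(sig)} significant of {len(df)} tested")
        lines.append("")
        if len(sig):
            lines.append("| miRNA | median fold-difference | FDR p |")
            lines.append("|---|---|---|")
            for r in sig.itertuples(index=False):
                lines.append(f"| {r.assay_id} | {r.median_fd:.2f} | {r.fdr_p:.2e} |")
            lines.append("")
    metrics_path = run_dir / "trees" / "diagnostic_metrics.csv"
    if metrics_path.exists():
        df = pd.read_csv(metrics_path)
        lines += ["## Diagnostic tree", "", df.to_markdown(index=False), ""]
    (run_dir / "report.md").write_text("\n".join(lines) + "\n")
    _write_provenance(run_dir, config, "report")


_STAGE_FN = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "hemolysis": stage_hemolysis,
    "normalize": stage_normalize,
    "de": stage_de,
    "survival": stage_survival,
    "trees": stage_trees,
    "report": stage_report,
}


def run_stage(stage: str, config: RunConfig, run_dir: str | Path) -> None:
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    try:
        _STAGE_FN[stage](config, run_dir)
    except MissingStageError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc


def run_pipeline(config: RunConfig, run_dir: str | Path) -> Path:
    """Execute all stages in order; partial outputs are retained on failure."""
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    for stage in STAGES:
        logger.info("running stage %s", stage)
        run_stage(stage, config, run_dir)
    return run_dir
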