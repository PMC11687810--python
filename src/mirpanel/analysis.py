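"""In-memory end-to-end analysis of one cohort (no file round-trips).

Mirrors the staged pipeline: inter-plate calibration, Ct ceiling, sample and
assay quality filters, hemolysis screening, endogenous-control selection,
comparative-Ct normalization and per-cohort differential expression, with
helpers for the survival and tree analyses.  Useful for simulation studies
where the same analysis is repeated over many synthetic cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .plates import (
    CtPlate, QcReport, SampleRecord, apply_ceiling, assay_prevalence_filter,
    ipc_correct, sample_detection_filter, spike_in_filter,
)
from .hemolysis import HemolysisVerdict, classify_samples, screen_matrix, UNAFFECTED
from .normalization import (
    ControlSet, NormalizedMatrix, eligible_candidates, normalize,
    normfinder_stability, prescreen_candidates, select_controls, StabilityResult,
)
from .diffexpr import DEResult, de_table
from .pipeline import RunConfig
from .survival import apply_horizon


@dataclass
class StudyResult:
    qc_report: QcReport
    ct: pd.DataFrame                      # post-QC calibrated, ceiled Ct
    statuses: dict
    verdicts: dict[str, HemolysisVerdict]
    stability: StabilityResult
    controls: ControlSet
    normalized: NormalizedMatrix
    de: dict[str, list[DEResult]]
    samples: list[SampleRecord]
    config: RunConfig

    def safe_assays(self) -> list[str]:
        """Hemolysis-unaffected, non-control assays (prognostic model input)."""
        values = self.normalized.non_control_values()
        return [a for a in values.columns
                if a in self.verdicts and self.verdicts[a].klass == UNAFFECTED]

    def case_ids(self) -> list[str]:
        idx = set(self.normalized.values.index)
        return [s.sample_id for s in self.samples
                if s.group == "case" and s.sample_id in idx]

    def endpoint(
        self, ids: Sequence[str], endpoint: str = "os"
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(time, event, kept ids) for an endpoint (os, dfi or a horizon key)."""
        by_id = {s.sample_id: s for s in self.samples}
        base = "dfi" if endpoint == "dfi" else "os"
        rows = [sid for sid in ids
                if getattr(by_id[sid], f"{base}_time") is not None]
        time = np.array([getattr(by_id[sid], f"{base}_time") for sid in rows])
        event = np.array([getattr(by_id[sid], f"{base}_event") for sid in rows])
        if endpoint in self.config.horizons:
            time, event = apply_horizon(time, event, self.config.horizons[endpoint])
        return time, event, rows


def analyze(
    plates: Sequence[CtPlate],
    samples: Sequence[SampleRecord],
    config: RunConfig | None = None,
) -> StudyResult:
    """Run QC, hemolysis screening, normalization and DE on one cohort."""
    config = config or RunConfig()
    config.validate()

    matrix, report = ipc_correct(plates)
    matrix = apply_ceiling(matrix, config.ceiling)
    spike_pass = spike_in_filter(samples, report)
    detect_pass = sample_detection_filter(matrix, report)
    kept_assays, _ = assay_prevalence_filter(matrix, report)
    keep = [s.sample_id for s in samples
            if spike_pass.get(s.sample_id, False)
            and detect_pass.get(s.sample_id, True)
            and s.sample_id in matrix.values.index]
    values = matrix.values.loc[keep, kept_assays]

    absorb = {s.sample_id: (s.a414, s.a375) for s in samples
              if s.sample_id in values.index
              and s.a414 is not None and s.a375 is not None}
    statuses = classify_samples(absorb)
    admitted = [sid for sid, st in statuses.items() if st.admitted]
    values = values.loc[[s for s in values.index if s in admitted]]
    a414 = {sid: ab[0] for sid, ab in absorb.items()}
    verdicts = {v.assay_id: v for v in screen_matrix(values, statuses, a414)}

    expressed_in_all = values.lt(config.ceiling).all(axis=0).to_dict()
    eligible, _ = eligible_candidates(
        values.columns, verdicts, expressed_in_all, config.control_whitelist
    )
    if len(eligible) < 3:
        raise ValueError("fewer than 3 eligible endogenous-control candidates")
    eligible = prescreen_candidates(values, eligible, config.normfinder_max_candidates)
    by_id = {s.sample_id: s for s in samples}
    groups = [by_id[sid].group for sid in values.index]
    stability = normfinder_stability(values[eligible], groups)
    controls = select_controls(
        stability, verdicts, expressed_in_all,
        whitelist=config.control_whitelist, v_threshold=config.v_threshold,
    )
    normalized = normalize(values, controls.assays, ceiling=config.ceiling)

    group_of = {s.sample_id: s.group for s in samples}
    cohort_of = {s.sample_id: s.cohort for s in samples}
    de = {
        cohort: de_table(normalized, group_of, cohort_of, cohort,
                         alpha=config.bh_alpha)
        for cohort in config.cohort.cohort_names
    }
    return StudyResult(
        qc_report=report, ct=values, statuses=statuses, verdicts=verdicts,
        stability=stability, controls=controls, normalized=normalized, de=de,
        samples=list(samples), config=config,
    )
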