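"""Synthetic RT-qPCR cohort generator.

Emulates the data structure of a multi-site circulating-miRNA panel study of
canine osteosarcoma: three case cohorts (default 35/13/13) against one
control group (default 21), a 56-assay custom panel with a handful of assays
near the detection limit, plate-specific calibration offsets removed by an
inter-plate calibrator, hemolysis-coupled assays whose Ct tracks 414 nm
absorbance, planted case/control expression shifts on the Ct scale, and
survival outcomes tied to selected miRNAs by a proportional-hazards
(exponential) model with independent censoring.

The generative model per well is Gaussian on the Ct scale:

    Ct(s, a) = base_a + effect_a * [s is case] + slope_a * A414_s
               + sample_shift_s + plate_offset_p + noise,  noise ~ N(0, sd_a)

Survival links are dichotomous: each linked miRNA contributes
``beta * [expression above the case median]`` to the log hazard, so the
event-rate ratio between the planted high/low groups is exactly
``exp(beta)`` — the quantity the downstream cutpoint + Cox analysis should
recover.  Everything is deterministic given the config seed, and the ground
truth (planted effects, coupling flags, hazard groups, latent hemolysis) is
returned for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .plates import CtPlate, SampleRecord

#: default planted case shift, Ct units (negative = upregulated;
#: -2.37 Ct is a ~5.2-fold increase)
DEFAULT_EFFECTS = {"miR-214-3p": -2.37}

#: default hemolysis couplings, Ct per 414 nm absorbance unit
DEFAULT_HEMOLYSIS = {"miR-16-5p": -3.0, "miR-451a": -3.5, "miR-92a-3p": -2.5}

#: default log-hazard coefficients of the survival links (HR 2.9)
DEFAULT_SURVIVAL_LINKS = {"miR-214-3p": math.log(2.9)}

#: assays generated with low variance and no group effect — endogenous-control
#: candidates the selection step should find
STABLE_ASSAYS = ["cfa-miR-23b", "rno-miR-223-3p", "hsa-miR-27b-3p"]

#: moderately stable assays (control-candidate padding material)
SEMI_STABLE_ASSAYS = ["hsa-let-7c-5p", "cfa-miR-140"]

#: assays generated near the detection limit (prevalence-filter fodder)
LOW_PREVALENCE_ASSAYS = ["miR-433-3p", "miR-210", "miR-589", "miR-551a",
                         "miR-138b", "miR-802"]

_NAMED_MARKERS = [
    "miR-214-3p", "miR-221", "miR-1307-3p", "miR-28-3p", "miR-222-3p",
    "miR-92b-3p", "miR-23a", "miR-133b", "miR-145-5p", "miR-133-3p",
    "miR-133c", "miR-378a-3p", "miR-30a", "miR-143-3p", "miR-125a",
    "miR-16-5p", "miR-451a", "miR-92a-3p",
]

#: instrument cycle range beyond which a well reads as undetected
DETECTION_LIMIT = 40.0

NTC_BASE_CT = 19.0


def default_assay_panel(n_assays: int = 56, n_low_prevalence: int = 6) -> list[str]:
    """Assay id list: named markers and controls first, filler assays after,
    low-prevalence assays last."""
    low = LOW_PREVALENCE_ASSAYS[:n_low_prevalence]
    if n_low_prevalence > len(LOW_PREVALENCE_ASSAYS):
        low = low + [f"miR-LP{i:02d}" for i in range(n_low_prevalence - len(low))]
    core = STABLE_ASSAYS + SEMI_STABLE_ASSAYS + [
        m for m in _NAMED_MARKERS if m not in STABLE_ASSAYS + SEMI_STABLE_ASSAYS
    ]
    n_core = n_assays - len(low)
    if n_core < 0:
        raise ValueError("more low-prevalence assays than assays")
    filler = [f"cfa-miR-9{i:02d}" for i in range(max(0, n_core - len(core)))]
    panel = (core + filler)[:n_core] + low
    return panel


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort; defaults mirror the emulated study."""

    n_cases_per_cohort: list[int] = field(default_factory=lambda: [35, 13, 13])
    cohort_names: list[str] = field(default_factory=lambda: ["OVC1", "OVC2", "CCOGC"])
    n_controls: int = 21
    n_assays: int = 56
    n_plates: int = 6
    plate_offsets: list[float] | None = None        # Ct units; drawn if None
    plate_offset_sd: float = 0.5
    planted_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    hemolysis_coupled: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HEMOLYSIS))
    survival_links: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SURVIVAL_LINKS))
    censor_rate: float = 0.2
    noise_sd: float = 0.8               # per-assay Ct noise, regular assays
    stable_noise_sd: float = 0.3        # noise of designated control candidates
    semi_stable_noise_sd: float = 0.45  # noise of the padding candidates
    sample_shift_sd: float = 0.5        # per-sample global Ct shift
    baseline_ct: dict[str, tuple[float, float]] | None = None  # assay -> (mean, sd)
    low_prevalence_assays: int = 6
    baseline_median_os: float = 300.0   # days, unlinked case
    baseline_median_dfi: float = 250.0
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_cases_per_cohort) or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if len(self.cohort_names) != len(self.n_cases_per_cohort):
            raise ValueError("cohort_names must match n_cases_per_cohort")
        if self.n_assays <= 0 or self.n_plates <= 0:
            raise ValueError("n_assays and n_plates must be positive")
        if self.low_prevalence_assays > self.n_assays:
            raise ValueError("more low-prevalence assays than assays")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        for nm in ("noise_sd", "stable_noise_sd", "plate_offset_sd"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if self.plate_offsets is not None and len(self.plate_offsets) != self.n_plates:
            raise ValueError("plate_offsets length must equal n_plates")
        panel = set(default_assay_panel(self.n_assays, self.low_prevalence_assays))
        if self.baseline_ct is not None:
            panel = set(self.baseline_ct)
        for name, mapping in (
            ("planted_effects", self.planted_effects),
            ("hemolysis_coupled", self.hemolysis_coupled),
            ("survival_links", self.survival_links),
        ):
            unknown = set(mapping) - panel
            if unknown:
                raise ValueError(f"{name} references unknown assays: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        if cfg.baseline_ct is not None:
            cfg.baseline_ct = {k: tuple(v) for k, v in cfg.baseline_ct.items()}
        return cfg


@dataclass
class GroundTruth:
    """Planted structure for recovery tests."""

    effects: dict[str, float]
    hemolysis_coupled: dict[str, float]
    survival_links: dict[str, float]
    stable_assays: list[str]
    low_prevalence_assays: list[str]
    a414: dict[str, float]
    hazard_group: dict[str, dict[str, int]]   # assay -> sample -> 0/1 (high)
    plate_offsets: dict[str, float]
    plate_of_sample: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _round4(x: float) -> float:
    return float(round(x, 4))


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[CtPlate], list[SampleRecord], GroundTruth]:
    """Generate plates, sample metadata and ground truth for one cohort draw."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    panel = default_assay_panel(config.n_assays, config.low_prevalence_assays)
    low_prev = panel[len(panel) - config.low_prevalence_assays:] if config.low_prevalence_assays else []
    stable = [a for a in STABLE_ASSAYS if a in panel]
    semi = [a for a in SEMI_STABLE_ASSAYS if a in panel]

    # per-assay baselines: controls and named markers are robustly expressed;
    # filler assays span up to near the ceiling, so (as in real plasma panels)
    # only a minority of assays is expressed in every sample
    named = set(_NAMED_MARKERS)
    if config.baseline_ct is not None:
        base = {a: config.baseline_ct[a] for a in panel}
    else:
        base = {}
        for a in panel:
            if a in stable:
                base[a] = (float(rng.uniform(20.0, 24.0)), config.stable_noise_sd)
            elif a in semi:
                base[a] = (float(rng.uniform(20.0, 24.0)), config.semi_stable_noise_sd)
            elif a in low_prev:
                base[a] = (float(rng.uniform(36.0, 38.0)), 1.0)
            elif a in named:
                base[a] = (float(rng.uniform(22.0, 30.0)), config.noise_sd)
            else:
                base[a] = (float(rng.uniform(24.0, 34.5)), config.noise_sd)

    # samples: cases per cohort, then controls
    sample_ids: list[str] = []
    cohort_of: dict[str, str] = {}
    group_of: dict[str, str] = {}
    for name, n in zip(config.cohort_names, config.n_cases_per_cohort):
        for i in range(n):
            sid = f"{name}-{i + 1:03d}"
            sample_ids.append(sid)
            cohort_of[sid] = name
            group_of[sid] = "case"
    for i in range(config.n_controls):
        sid = f"CTRL-{i + 1:03d}"
        sample_ids.append(sid)
        cohort_of[sid] = "CTRL"
        group_of[sid] = "control"
    n_samples = len(sample_ids)

    # hemolysis latents: 414 nm from a short-tailed mixture, ratio mostly ~1.6
    # with a lipemic subgroup below 1.4
    u = rng.random(n_samples)
    a414 = np.where(
        u < 0.75,
        rng.uniform(0.05, 0.2, n_samples),
        rng.uniform(0.2, 1.2, n_samples),
    )
    lipemic = rng.random(n_samples) < 0.1
    ratio = np.where(
        lipemic,
        rng.normal(1.25, 0.06, n_samples),
        rng.normal(1.6, 0.08, n_samples),
    )
    ratio = np.clip(ratio, 1.05, 2.2)
    a375 = a414 / ratio

    sample_shift = rng.normal(0.0, config.sample_shift_sd, n_samples)
    # spike-ins emulate runs whose isolation/RT efficiency is in control:
    # a bounded spread keeps every draw within +/- 2 SD of the sample mean
    spike_iso = rng.uniform(19.6, 20.4, n_samples)
    spike_rt = rng.uniform(20.6, 21.4, n_samples)

    # plate assignment (round robin) and offsets
    plate_ids = [f"P{p + 1:02d}" for p in range(config.n_plates)]
    if config.plate_offsets is not None:
        offsets = {pid: float(o) for pid, o in zip(plate_ids, config.plate_offsets)}
    else:
        draw = rng.normal(0.0, config.plate_offset_sd, config.n_plates)
        offsets = {pid: float(o) for pid, o in zip(plate_ids, draw)}
    plate_of = {sid: plate_ids[i % config.n_plates] for i, sid in enumerate(sample_ids)}

    # core Ct signal (before plate offset), cases carry the planted shifts;
    # `biological` is the shift-free part: the per-sample signal that survives
    # control normalization, used for the hazard link
    is_case = np.array([group_of[s] == "case" for s in sample_ids])
    core = np.empty((n_samples, len(panel)))
    biological = np.empty((n_samples, len(panel)))
    for j, a in enumerate(panel):
        mean, sd = base[a]
        col = mean + rng.normal(0.0, sd, n_samples)
        if a in config.planted_effects:
            col = col + config.planted_effects[a] * is_case
        if a in config.hemolysis_coupled:
            col = col + config.hemolysis_coupled[a] * a414
        biological[:, j] = col
        core[:, j] = col + sample_shift

    # survival: dichotomous hazard groups from realized abundance (-Ct) of the
    # normalization-recoverable signal
    case_idx = np.nonzero(is_case)[0]
    hazard_group: dict[str, dict[str, int]] = {}
    log_hr = np.zeros(n_samples)
    for a, beta in config.survival_links.items():
        j = panel.index(a)
        abundance = -biological[:, j]
        med = float(np.median(abundance[case_idx]))
        z = (abundance > med).astype(int)
        hazard_group[a] = {sample_ids[i]: int(z[i]) for i in case_idx}
        log_hr += beta * z

    lam_os = math.log(2.0) / config.baseline_median_os
    lam_dfi = math.log(2.0) / config.baseline_median_dfi
    rate_os = lam_os * np.exp(log_hr)
    rate_dfi = lam_dfi * np.exp(log_hr)
    t_os = rng.exponential(1.0 / rate_os)
    t_dfi = rng.exponential(1.0 / rate_dfi)
    if config.censor_rate > 0:
        c = config.censor_rate
        lam_c_os = float(np.mean(rate_os[case_idx])) * c / (1 - c)
        lam_c_dfi = float(np.mean(rate_dfi[case_idx])) * c / (1 - c)
        c_os = rng.exponential(1.0 / lam_c_os, n_samples)
        c_dfi = rng.exponential(1.0 / lam_c_dfi, n_samples)
    else:
        c_os = np.full(n_samples, np.inf)
        c_dfi = np.full(n_samples, np.inf)
    os_event = (t_os <= c_os).astype(int)
    dfi_event = (t_dfi <= c_dfi).astype(int)
    os_time = np.ceil(np.minimum(t_os, c_os)).astype(float)
    dfi_time = np.ceil(np.minimum(t_dfi, c_dfi)).astype(float)

    # clinical covariates (plumbing for the multivariable models)
    age = rng.uniform(3.0, 12.0, n_samples)
    weight = rng.uniform(20.0, 65.0, n_samples)
    sexes = rng.choice(["male_neutered", "female_spayed", "male_intact", "female_intact"],
                       size=n_samples, p=[0.45, 0.45, 0.05, 0.05])
    locations = rng.choice(["radius", "humerus", "femur", "tibia"],
                           size=n_samples, p=[0.4, 0.25, 0.2, 0.15])
    alp = rng.choice(["within", "above", "below"], size=n_samples, p=[0.6, 0.3, 0.1])

    samples: list[SampleRecord] = []
    for i, sid in enumerate(sample_ids):
        case = group_of[sid] == "case"
        samples.append(
            SampleRecord(
                sample_id=sid,
                cohort=cohort_of[sid],
                group=group_of[sid],
                a414=_round4(a414[i]),
                a375=_round4(a375[i]),
                spike_iso=_round4(spike_iso[i]),
                spike_rt=_round4(spike_rt[i]),
                age=_round4(age[i]),
                sex=str(sexes[i]),
                weight=_round4(weight[i]),
                tumour_location=str(locations[i]) if case else None,
                alp_status=str(alp[i]) if case else None,
                os_time=float(os_time[i]) if case else None,
                os_event=int(os_event[i]) if case else None,
                dfi_time=float(dfi_time[i]) if case else None,
                dfi_event=int(dfi_event[i]) if case else None,
            )
        )

    # plates: wells carry core + plate offset; above the detection limit the
    # instrument reports no Ct
    plates: list[CtPlate] = []
    for p, pid in enumerate(plate_ids):
        rows = []
        members = [i for i, sid in enumerate(sample_ids) if plate_of[sid] == pid]
        for i in members:
            for j, a in enumerate(panel):
                ct = core[i, j] + offsets[pid]
                detected = ct <= DETECTION_LIMIT
                rows.append(
                    {
                        "sample_id": sample_ids[i],
                        "assay_id": a,
                        "ct": _round4(ct) if detected else math.nan,
                        "curve_ok": True,
                    }
                )
        ntc = [_round4(NTC_BASE_CT + offsets[pid] + rng.normal(0.0, 0.05)) for _ in range(6)]
        wells = pd.DataFrame(rows, columns=["sample_id", "assay_id", "ct", "curve_ok"])
        plates.append(CtPlate(plate_id=pid, wells=wells, ntc_calibrator=ntc))

    truth = GroundTruth(
        effects=dict(config.planted_effects),
        hemolysis_coupled=dict(config.hemolysis_coupled),
        survival_links=dict(config.survival_links),
        stable_assays=stable[:3],
        low_prevalence_assays=list(low_prev),
        a414={sid: _round4(a414[i]) for i, sid in enumerate(sample_ids)},
        hazard_group=hazard_group,
        plate_offsets=offsets,
        plate_of_sample=plate_of,
    )
    return plates, samples, truth


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return format(v, ".4f").rstrip("0").rstrip(".")
    return str(v)


def write_fixture(
    plates: Sequence[CtPlate],
    samples: Sequence[SampleRecord],
    dir_path: str | Path,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write plate and metadata CSVs in the dialect the readers expect.

    One CSV per plate (calibrator wells flagged with ``is_ntc_calibrator``)
    plus ``samples.csv``; deterministic formatting, so a fixed seed produces
    byte-identical files.  Returns the written paths.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    plate_cols = ["plate_id", "sample_id", "assay_id", "ct", "curve_ok", "is_ntc_calibrator"]
    for p in plates:
        path = out / f"plate_{p.plate_id}.csv"
        lines = [",".join(plate_cols)]
        for r in p.wells.itertuples(index=False):
            lines.append(
                ",".join([p.plate_id, r.sample_id, r.assay_id, _fmt(r.ct),
                          _fmt(bool(r.curve_ok)), "False"])
            )
        for ct in p.ntc_calibrator:
            lines.append(",".join([p.plate_id, "NTC", "UniSp3", _fmt(ct), "True", "True"]))
        path.write_text("\n".join(lines) + "\n")
        written[f"plate_{p.plate_id}"] = path

    meta_cols = ["sample_id", "cohort", "group", "a414", "a375", "spike_iso",
                 "spike_rt", "age", "sex", "weight", "tumour_location",
                 "alp_status", "os_time", "os_event", "dfi_time", "dfi_event"]
    lines = [",".join(meta_cols)]
    for s in samples:
        lines.append(",".join(_fmt(getattr(s, c)) for c in meta_cols))
    meta = out / "samples.csv"
    meta.write_text("\n".join(lines) + "\n")
    written["samples"] = meta

    if truth is not None:
        tpath = out / "truth.json"
        truth.to_json(tpath)
        written["truth"] = tpath
    return written
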