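"""Plate import, inter-plate calibration and quality filters.

RT-qPCR panels are run one plate per batch of samples; each plate carries a
synthetic inter-plate calibrator (IPC) template in no-template-control (NTC)
wells.  Plate-to-plate Ct offsets are removed by subtracting, from every well
on a plate, the difference between that plate's mean calibrator Ct and the
grand mean of the per-plate calibrator means.  After calibration a hard Ct
ceiling is applied (undetected wells, wells above the ceiling and wells with a
rejected amplification curve are all set to the ceiling), and three quality
filters are run on the combined data set:

* spike-in filter     — both processing spike-ins of a sample must lie within
                        mean +/- 2 SD of that spike-in over all samples;
* detection filter    — a sample's count of detected assays must be at least
                        mean - 2 SD of the counts over all samples;
* prevalence filter   — an assay detected in fewer samples than
                        mean - 2 SD of the per-assay counts is dropped.

Filter statistics are computed once on the full input set before any
exclusion, so the pass/fail partition does not depend on processing order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default Ct ceiling, in cycles
DEFAULT_CEILING = 35.00

#: tokens in the Ct column that denote an undetected well
MISSING_CT_TOKENS = {"", "undetermined", "na", "nan", ">35"}

PLATE_COLUMNS = {"plate_id", "sample_id", "assay_id", "ct"}
OPTIONAL_PLATE_COLUMNS = {"curve_ok", "is_ntc_calibrator"}

SAMPLE_COLUMNS = {"sample_id", "cohort", "group"}


class PlateFormatError(ValueError):
    """Raised when a plate or metadata export cannot be interpreted."""


@dataclass
class CtPlate:
    """Raw Ct values for one PCR array.

    ``wells`` has one row per (sample, assay) well with columns ``sample_id``,
    ``assay_id``, ``ct`` (float, NaN when undetected) and ``curve_ok`` (bool).
    ``ntc_calibrator`` holds the calibrator Ct replicates (typically 6).
    """

    plate_id: str
    wells: pd.DataFrame
    ntc_calibrator: list[float]

    def __post_init__(self) -> None:
        if len(self.ntc_calibrator) == 0:
            raise ValueError(f"plate {self.plate_id!r}: no NTC calibrator replicates")
        ct = self.wells["ct"]
        bad = ct[(ct <= 0) | (ct >= 50)].dropna()
        if len(bad):
            raise ValueError(
                f"plate {self.plate_id!r}: Ct values outside (0, 50): {sorted(bad)[:5]}"
            )


@dataclass
class CtMatrix:
    """Samples x assays grid of (calibrated) Ct values.

    ``ceiling_mask`` marks cells forced to the ceiling; before
    :func:`apply_ceiling` it is all-False and ``values`` may contain NaN.
    ``curve_ok`` carries the per-well amplification-curve flag.
    """

    values: pd.DataFrame
    ceiling_mask: pd.DataFrame
    ceiling: float = DEFAULT_CEILING
    curve_ok: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    def detected(self) -> pd.DataFrame:
        """Boolean grid: Ct strictly below the ceiling and not masked."""
        return self.values.lt(self.ceiling) & ~self.ceiling_mask & self.values.notna()


@dataclass
class SampleRecord:
    """Per-sample metadata: identity, QC readings, clinical covariates, outcomes."""

    sample_id: str
    cohort: str
    group: str  # "case" or "control"
    a414: float | None = None
    a375: float | None = None
    spike_iso: float | None = None
    spike_rt: float | None = None
    age: float | None = None
    sex: str | None = None
    weight: float | None = None
    tumour_location: str | None = None
    alp_status: str | None = None
    os_time: float | None = None
    os_event: int | None = None
    dfi_time: float | None = None
    dfi_event: int | None = None

    def __post_init__(self) -> None:
        for name in ("a414", "a375"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v <= 0:
                raise ValueError(f"sample {self.sample_id!r}: {name} must be > 0")
        for name in ("os_time", "dfi_time"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise ValueError(f"sample {self.sample_id!r}: {name} must be >= 0")
        for name in ("os_event", "dfi_event"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(f"sample {self.sample_id!r}: {name} must be 0/1")


@dataclass
class QcReport:
    """Audit trail of calibration offsets and exclusions.

    Every exclusion carries exactly one primary reason code, one of
    ``missing_spike``, ``spike_out_of_range``, ``low_detection``,
    ``low_prevalence``.
    """

    plate_offsets: dict[str, float] = field(default_factory=dict)
    excluded_samples: list[dict] = field(default_factory=list)
    excluded_assays: list[dict] = field(default_factory=list)

    def exclude_sample(self, sample_id: str, reason: str, detail: str = "") -> None:
        self.excluded_samples.append(
            {"sample_id": sample_id, "reason": reason, "detail": detail}
        )

    def exclude_assay(self, assay_id: str, reason: str, detail: str = "") -> None:
        self.excluded_assays.append(
            {"assay_id": assay_id, "reason": reason, "detail": detail}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    def summary(self) -> str:
        lines = ["plate offsets (Ct):"]
        for pid, off in sorted(self.plate_offsets.items()):
            lines.append(f"  {pid}: {off:+.3f}")
        lines.append(f"excluded samples: {len(self.excluded_samples)}")
        for e in self.excluded_samples:
            lines.append(f"  {e['sample_id']}: {e['reason']} {e['detail']}")
        lines.append(f"excluded assays: {len(self.excluded_assays)}")
        for e in self.excluded_assays:
            lines.append(f"  {e['assay_id']}: {e['reason']} {e['detail']}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_ct(token, file: str, line: int) -> float:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return math.nan
    s = str(token).strip()
    if s.lower() in MISSING_CT_TOKENS:
        return math.nan
    try:
        return float(s)
    except ValueError:
        raise PlateFormatError(f"{file}:{line}: unparseable Ct value {s!r}") from None


def _parse_bool(token, default: bool) -> bool:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return default
    s = str(token).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    return default


def read_plates(paths: Iterable[str | Path]) -> list[CtPlate]:
    """Read long-format plate CSV exports into :class:`CtPlate` objects.

    Required columns: ``plate_id, sample_id, assay_id, ct``.  Optional:
    ``curve_ok`` (defaults to True — curve review is a manual step and the
    flag is its hook) and ``is_ntc_calibrator``.  Unknown columns are ignored
    with a warning.  Missing-Ct tokens: empty field, ``Undetermined``, ``NA``,
    ``>35``.  A duplicated (sample, assay) well on a plate is an error.
    """
    plates: dict[str, dict] = {}
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = PLATE_COLUMNS - set(df.columns)
        if missing:
            raise PlateFormatError(f"{path}: missing required columns {sorted(missing)}")
        unknown = set(df.columns) - PLATE_COLUMNS - OPTIONAL_PLATE_COLUMNS
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", path, sorted(unknown))
        has_curve = "curve_ok" in df.columns
        has_ntc = "is_ntc_calibrator" in df.columns
        for i, row in enumerate(df.itertuples(index=False), start=2):
            rec = row._asdict()
            pid = rec["plate_id"].strip()
            if not pid:
                raise PlateFormatError(f"{path}:{i}: empty plate_id")
            entry = plates.setdefault(pid, {"wells": [], "ntc": [], "seen": set()})
            ct = _parse_ct(rec["ct"], str(path), i)
            if has_ntc and _parse_bool(rec.get("is_ntc_calibrator"), False):
                if math.isnan(ct):
                    raise PlateFormatError(f"{path}:{i}: NTC calibrator well without Ct")
                entry["ntc"].append(ct)
                continue
            key = (rec["sample_id"], rec["assay_id"])
            if key in entry["seen"]:
                raise PlateFormatError(
                    f"{path}:{i}: duplicated well {key} on plate {pid!r}"
                )
            entry["seen"].add(key)
            entry["wells"].append(
                {
                    "sample_id": rec["sample_id"],
                    "assay_id": rec["assay_id"],
                    "ct": ct,
                    "curve_ok": _parse_bool(rec.get("curve_ok"), True) if has_curve else True,
                }
            )
    out = []
    for pid in sorted(plates):
        entry = plates[pid]
        wells = pd.DataFrame(entry["wells"], columns=["sample_id", "assay_id", "ct", "curve_ok"])
        out.append(CtPlate(plate_id=pid, wells=wells, ntc_calibrator=entry["ntc"]))
    return out


_FLOAT_FIELDS = ("a414", "a375", "spike_iso", "spike_rt", "age", "weight",
                 "os_time", "dfi_time")
_STR_FIELDS = ("cohort", "group", "sex", "tumour_location", "alp_status")


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read the per-sample metadata CSV.  Missing values are blank fields."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = SAMPLE_COLUMNS - set(df.columns)
    if missing:
        raise PlateFormatError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        kwargs: dict = {"sample_id": row["sample_id"]}
        for name in _STR_FIELDS:
            v = row.get(name, "").strip()
            kwargs[name] = v if v else None
        if kwargs["cohort"] is None or kwargs["group"] is None:
            raise PlateFormatError(f"{path}:{i}: cohort/group required")
        for name in _FLOAT_FIELDS:
            v = row.get(name, "").strip()
            if v == "" or v.lower() in ("na", "nan"):
                kwargs[name] = None
            else:
                try:
                    kwargs[name] = float(v)
                except ValueError:
                    raise PlateFormatError(
                        f"{path}:{i}: unparseable value {v!r} in column {name}"
                    ) from None
        for name in ("os_event", "dfi_event"):
            v = row.get(name, "").strip()
            kwargs[name] = int(float(v)) if v not in ("", "na", "NA") else None
        records.append(SampleRecord(**kwargs))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        raise PlateFormatError(f"{path}: duplicated sample ids {dups}")
    return records


def samples_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabular view of sample records, indexed by sample id."""
    df = pd.DataFrame([asdict(s) for s in samples])
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# calibration and ceiling
# ---------------------------------------------------------------------------

def ipc_correct(plates: Sequence[CtPlate]) -> tuple[CtMatrix, QcReport]:
    """Remove plate-to-plate offsets using the inter-plate calibrator.

    offset_p = mean(calibrator Ct on plate p) - grand mean of the per-plate
    calibrator means; every Ct on plate p (calibrator wells included) is
    corrected by subtracting offset_p.  After correction the per-plate
    calibrator means all equal the grand mean.
    """
    if not plates:
        raise ValueError("no plates")
    plate_means = {p.plate_id: float(np.mean(p.ntc_calibrator)) for p in plates}
    grand = float(np.mean(list(plate_means.values())))
    report = QcReport(plate_offsets={pid: m - grand for pid, m in plate_means.items()})

    frames = []
    for p in plates:
        w = p.wells.copy()
        w["ct"] = w["ct"] - report.plate_offsets[p.plate_id]
        frames.append(w)
    long = pd.concat(frames, ignore_index=True)
    dup = long.duplicated(["sample_id", "assay_id"])
    if dup.any():
        pairs = long.loc[dup, ["sample_id", "assay_id"]].drop_duplicates()
        raise ValueError(
            "sample/assay wells present on more than one plate: "
            + ", ".join(f"({r.sample_id}, {r.assay_id})" for r in pairs.itertuples())
        )
    values = long.pivot(index="sample_id", columns="assay_id", values="ct").sort_index()
    curve = (
        long.pivot(index="sample_id", columns="assay_id", values="curve_ok")
        .sort_index()
        .fillna(True)
        .astype(bool)
    )
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return CtMatrix(values=values, ceiling_mask=mask, curve_ok=curve), report


def apply_ceiling(matrix: CtMatrix, ceiling: float = DEFAULT_CEILING) -> CtMatrix:
    """Force undetected, above-ceiling and bad-curve wells to exactly ``ceiling``.

    Cells at the ceiling are treated as non-detections downstream; the mask
    records which cells were forced.  Idempotent.
    """
    values = matrix.values.copy()
    curve = (
        matrix.curve_ok
        if matrix.curve_ok is not None
        else pd.DataFrame(True, index=values.index, columns=values.columns)
    )
    mask = values.isna() | values.gt(ceiling) | ~curve | matrix.ceiling_mask
    values = values.mask(mask, ceiling)
    return CtMatrix(values=values, ceiling_mask=mask, ceiling=ceiling, curve_ok=curve)


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------

def _two_sd_band(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean - 2.0 * sd, mean + 2.0 * sd


def spike_in_filter(
    samples: Sequence[SampleRecord], report: QcReport | None = None
) -> dict[str, bool]:
    """Pass samples whose isolation and RT spike-in Cts lie within +/- 2 SD.

    The mean/SD of each spike-in are computed once over all samples with a
    reading.  A missing spike-in fails the sample (reason ``missing_spike``).
    With a single sample or zero spread everything passes — there is no
    evidence of deviation to act on.
    """
    result: dict[str, bool] = {}
    bands = {}
    for field_name in ("spike_iso", "spike_rt"):
        obs = np.array(
            [getattr(s, field_name) for s in samples if getattr(s, field_name) is not None],
            dtype=float,
        )
        bands[field_name] = _two_sd_band(obs) if len(obs) > 1 else None
    for s in samples:
        missing = [f for f in ("spike_iso", "spike_rt") if getattr(s, f) is None]
        if missing:
            result[s.sample_id] = False
            if report is not None:
                report.exclude_sample(s.sample_id, "missing_spike", ",".join(missing))
            continue
        ok = True
        detail = []
        for field_name in ("spike_iso", "spike_rt"):
            band = bands[field_name]
            if band is None:
                continue
            lo, hi = band
            v = getattr(s, field_name)
            if not (lo <= v <= hi):
                ok = False
                detail.append(f"{field_name}={v:.2f} outside [{lo:.2f}, {hi:.2f}]")
        result[s.sample_id] = ok
        if not ok and report is not None:
            report.exclude_sample(s.sample_id, "spike_out_of_range", "; ".join(detail))
    return result


def sample_detection_filter(
    matrix: CtMatrix, report: QcReport | None = None
) -> dict[str, bool]:
    """Pass samples whose detected-assay count is >= mean - 2 SD of all counts."""
    counts = matrix.detected().sum(axis=1).astype(float)
    if len(counts) <= 1:
        return {sid: True for sid in matrix.sample_ids}
    lo, _ = _two_sd_band(counts.to_numpy())
    result = {}
    for sid, c in counts.items():
        ok = bool(c >= lo)  # boundary meets the threshold
        result[sid] = ok
        if not ok and report is not None:
            report.exclude_sample(
                sid, "low_detection", f"detected {int(c)} assays, threshold {lo:.2f}"
            )
    return result


def assay_prevalence_filter(
    matrix: CtMatrix, report: QcReport | None = None
) -> tuple[list[str], list[str]]:
    """Drop assays detected in fewer samples than mean - 2 SD of the counts.

    Returns (kept, dropped).  With a single assay the SD is undefined and the
    assay is kept.
    """
    prevalence = matrix.detected().sum(axis=0).astype(float)
    if len(prevalence) <= 1:
        return list(matrix.assay_ids), []
    lo, _ = _two_sd_band(prevalence.to_numpy())
    kept, dropped = [], []
    for aid, c in prevalence.items():
        if c < lo:
            dropped.append(aid)
            if report is not None:
                report.exclude_assay(
                    aid, "low_prevalence", f"detected in {int(c)} samples, threshold {lo:.2f}"
                )
        else:
            kept.append(aid)
    return kept, dropped
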