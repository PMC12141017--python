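"""Longitudinal dose/observation data model and rectangular CSV I/O.

The study design this package targets is a continuous-infusion
anticoagulation trial: each subject carries a piecewise-constant infusion
history (mg/h of nafamostat mesylate), timed concentration observations
(μg/L) drawn from one of two sampling sites (patient central vein or ECMO
circuit), and timed aPTT observations (seconds).  Everything downstream —
structural models, mixed-effects estimation, diagnostics, simulation —
consumes the containers defined here.

Times are hours since the first dose throughout the package; input files
may declare minutes (``TIMEU``) and are converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import NamedTuple

import pandas as pd

__all__ = [
    "ObsKind",
    "Site",
    "DoseEvent",
    "Observation",
    "Subject",
    "StudyDataset",
    "ValidationError",
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "filter_blq",
    "BlqFilterResult",
    "LLOQ_UG_PER_L",
]

#: Lower limit of quantitation of the LC-MS/MS assay, μg/L.  Concentration
#: records below this are flagged BLQ and dropped from estimation copies.
LLOQ_UG_PER_L = 0.5


class ValidationError(ValueError):
    """A dataset or record violates a structural invariant."""


class SchemaError(ValueError):
    """An input file is missing mandatory columns or uses unknown codes."""


class ObsKind(str, Enum):
    CONCENTRATION = "concentration"
    APTT = "aptt"


class Site(str, Enum):
    PATIENT = "patient"
    ECMO = "ecmo"
    MIXED = "mixed"  # dataset-level only


@dataclass(frozen=True)
class DoseEvent:
    """Constant-rate infusion segment over ``[start_time, end_time)``.

    Parameters
    ----------
    start_time, end_time : float
        Hours since first dose.  ``end_time`` may be ``math.inf`` for an
        open-ended segment (encoded as end-of-study on write).
    rate : float
        Infusion rate in mg/h of nafamostat mesylate.
    """

    start_time: float
    end_time: float
    rate: float

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValidationError(f"dose start_time {self.start_time} < 0")
        if not self.end_time > self.start_time:
            raise ValidationError(
                f"dose end_time {self.end_time} must exceed start_time {self.start_time}"
            )
        if self.rate < 0:
            raise ValidationError(f"dose rate {self.rate} < 0")


@dataclass(frozen=True)
class Observation:
    """A timed measurement: concentration (μg/L) or aPTT (s).

    ``blq`` marks a concentration below the assay LLOQ; it is only
    meaningful for ``kind == ObsKind.CONCENTRATION``.
    """

    time: float
    value: float
    kind: ObsKind
    blq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"observation time {self.time} < 0")
        if not self.blq and self.value < 0:
            raise ValidationError(f"observation value {self.value} < 0")
        if self.blq and self.kind is not ObsKind.CONCENTRATION:
            raise ValidationError("blq flag is only meaningful for concentrations")


@dataclass
class Subject:
    """One study participant: covariates, dosing history, observations."""

    id: str
    site: Site
    covariates: dict[str, float | str] = field(default_factory=dict)
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("subject id must be non-empty")
        gfr = self.covariates.get("gas_flow_rate")
        if gfr is not None and not float(gfr) > 0:
            raise ValidationError(f"subject {self.id}: gas_flow_rate must be > 0")
        prev_end = -math.inf
        prev_start = -math.inf
        for d in self.doses:
            if d.start_time < prev_start:
                raise ValidationError(f"subject {self.id}: dose events not sorted")
            if d.start_time < prev_end:
                raise ValidationError(f"subject {self.id}: overlapping dose events")
            prev_start, prev_end = d.start_time, d.end_time
        t_prev = -math.inf
        for i, o in enumerate(self.observations):
            if o.time < t_prev:
                raise ValidationError(
                    f"subject {self.id}: observations not sorted by time (row {i})"
                )
            t_prev = o.time

    def observations_of(self, kind: ObsKind) -> list[Observation]:
        return [o for o in self.observations if o.kind is kind]

    @property
    def end_of_study(self) -> float:
        times = [o.time for o in self.observations]
        times += [d.end_time for d in self.doses if math.isfinite(d.end_time)]
        return max(times, default=0.0)


@dataclass
class StudyDataset:
    """A collection of subjects sharing one rectangular layout."""

    subjects: list[Subject] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for s in self.subjects:
            if s.id in seen:
                raise ValidationError(f"duplicate subject id {s.id!r}")
            seen.add(s.id)
            s.validate()

    @property
    def site(self) -> Site:
        sites = {s.site for s in self.subjects}
        if len(sites) == 1:
            return next(iter(sites))
        return Site.MIXED

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def n_observations(self, kind: ObsKind | None = None) -> int:
        if kind is None:
            return sum(len(s.observations) for s in self.subjects)
        return sum(len(s.observations_of(kind)) for s in self.subjects)


# ---------------------------------------------------------------------------
# CSV dialect
#
# Mandatory columns: ID, TIME, EVID (0 observation / 1 dose), RATE (mg/h on
# dose rows), DV, DVID (1 concentration μg/L, 2 aPTT s), BLQ (0/1), SITE
# (patient|ecmo).  Optional: TIMEU (min|h, default h), TEND (dose end time,
# empty = open-ended), covariate columns.

_MANDATORY = ["ID", "TIME", "EVID", "RATE", "DV", "DVID", "BLQ", "SITE"]

#: column name <-> covariate key for the covariates the study recorded
COVARIATE_COLUMNS = {
    "GASFLOW": "gas_flow_rate",
    "SEX": "sex",
    "AGE": "age",
    "WEIGHT": "weight",
    "HEIGHT": "height",
    "ALBUMIN": "albumin",
    "CREATININE": "creatinine",
    "BILIRUBIN": "bilirubin",
    "CRP": "crp",
    "BUN": "bun",
    "ECMOTYPE": "ecmo_type",
    "PUMPSPEED": "pump_speed",
    "BLOODFLOW": "blood_flow_rate",
    "FIO2": "fio2",
    "SHOCK": "shock",
    "HTN": "hypertension",
    "DM": "diabetes",
    "ICUDAYS": "icu_days",
    "MVDAYS": "mv_days",
}
_COV_TO_COLUMN = {v: k for k, v in COVARIATE_COLUMNS.items()}

_KIND_TO_DVID = {ObsKind.CONCENTRATION: 1, ObsKind.APTT: 2}
_DVID_TO_KIND = {1: ObsKind.CONCENTRATION, 2: ObsKind.APTT}


def _time_factor(unit: str) -> float:
    unit = str(unit).strip().lower()
    if unit in ("h", "hr", "hour", "hours"):
        return 1.0
    if unit in ("min", "m", "minute", "minutes"):
        return 1.0 / 60.0
    raise SchemaError(f"unknown time unit {unit!r} (expected 'min' or 'h')")


def read_dataset(path, format: str = "csv") -> StudyDataset:
    """Read a rectangular study file into a validated :class:`StudyDataset`.

    Parameters
    ----------
    path : path-like
    format : {"csv", "nonmem"}
        ``"csv"`` is the package dialect (explicit TEND dose end times).
        ``"nonmem"`` is a shim for the AMT/RATE duality: dose rows carry
        AMT (mg) and RATE (mg/h) and the segment length is AMT/RATE.
    """
    if format not in ("csv", "nonmem"):
        raise SchemaError(f"unknown format {format!r}")
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if format == "nonmem":
        missing = [c for c in missing if c != "TEND"]
        if "AMT" not in df.columns:
            missing.append("AMT")
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    cov_cols = [c for c in df.columns if c in COVARIATE_COLUMNS]
    subjects: list[Subject] = []
    for sid, grp in df.groupby("ID", sort=False):
        sid = str(sid)
        factors = (
            grp["TIMEU"].map(_time_factor)
            if "TIMEU" in grp.columns
            else pd.Series(1.0, index=grp.index)
        )
        site_vals = set(grp["SITE"].astype(str).str.lower())
        if len(site_vals) != 1:
            raise ValidationError(f"subject {sid}: inconsistent SITE values")
        site = Site(next(iter(site_vals)))

        covariates: dict[str, float | str] = {}
        for col in cov_cols:
            vals = grp[col].dropna()
            if len(vals):
                v = vals.iloc[0]
                key = COVARIATE_COLUMNS[col]
                try:
                    covariates[key] = float(v)
                except (TypeError, ValueError):
                    covariates[key] = str(v)

        doses: list[DoseEvent] = []
        observations: list[Observation] = []
        for idx, row in grp.iterrows():
            f = factors.loc[idx]
            t = float(row["TIME"]) * f
            if t < 0:
                raise ValidationError(f"subject {sid}: negative TIME at row {idx}")
            if int(row["EVID"]) == 1:
                rate = float(row["RATE"])
                if format == "nonmem":
                    amt = float(row["AMT"])
                    end = t + amt / rate if rate > 0 else math.inf
                else:
                    tend = row.get("TEND")
                    end = (
                        float(tend) * f
                        if tend is not None and not pd.isna(tend)
                        else math.inf
                    )
                doses.append(DoseEvent(start_time=t, end_time=end, rate=rate))
            else:
                kind = _DVID_TO_KIND.get(int(row["DVID"]))
                if kind is None:
                    raise SchemaError(
                        f"subject {sid}: unknown DVID {row['DVID']} at row {idx}"
                    )
                blq = bool(int(row["BLQ"])) if not pd.isna(row["BLQ"]) else False
                observations.append(
                    Observation(time=t, value=float(row["DV"]), kind=kind, blq=blq)
                )
        # open-ended final dose: close it at end of study for a well-defined
        # piecewise-constant infusion function
        observations.sort(key=lambda o: o.time)
        subjects.append(
            Subject(
                id=sid,
                site=site,
                covariates=covariates,
                doses=doses,
                observations=observations,
            )
        )
    return StudyDataset(subjects=subjects)


def write_dataset(ds: StudyDataset, path) -> None:
    """Emit the same rectangular CSV dialect :func:`read_dataset` accepts.

    Times are written in hours.  Open-ended dose events get an empty TEND.
    """
    ds.validate()
    cov_keys: list[str] = []
    for s in ds.subjects:
        for k in s.covariates:
            if k not in cov_keys:
                cov_keys.append(k)
    cov_cols = [_COV_TO_COLUMN.get(k, k.upper()) for k in cov_keys]

    rows = []
    for s in ds.subjects:
        covs = {
            col: s.covariates.get(k, "") for col, k in zip(cov_cols, cov_keys)
        }
        for d in s.doses:
            rows.append(
                {
                    "ID": s.id,
                    "TIME": d.start_time,
                    "TIMEU": "h",
                    "EVID": 1,
                    "RATE": d.rate,
                    "TEND": d.end_time if math.isfinite(d.end_time) else "",
                    "DV": "",
                    "DVID": "",
                    "BLQ": 0,
                    "SITE": s.site.value,
                    **covs,
                }
            )
        for o in s.observations:
            rows.append(
                {
                    "ID": s.id,
                    "TIME": o.time,
                    "TIMEU": "h",
                    "EVID": 0,
                    "RATE": "",
                    "TEND": "",
                    "DV": o.value,
                    "DVID": _KIND_TO_DVID[o.kind],
                    "BLQ": int(o.blq),
                    "SITE": s.site.value,
                    **covs,
                }
            )
    columns = _MANDATORY[:2] + ["TIMEU", "EVID", "RATE", "TEND", "DV", "DVID", "BLQ", "SITE"] + cov_cols
    # dedupe while preserving order
    columns = list(dict.fromkeys(columns))
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


class BlqFilterResult(NamedTuple):
    dataset: StudyDataset
    n_removed: int


def filter_blq(ds: StudyDataset, lloq: float = LLOQ_UG_PER_L) -> BlqFilterResult:
    """Drop below-LLOQ concentration records (M1 handling).

    Concentration observations with ``value < lloq`` (or already flagged
    ``blq``) are removed; aPTT observations are untouched.  Returns the
    filtered copy and the number of removed records.  Idempotent.
    """
    if not lloq > 0:
        raise ValidationError(f"lloq must be > 0, got {lloq}")
    removed = 0
    subjects = []
    for s in ds.subjects:
        kept: list[Observation] = []
        for o in s.observations:
            if o.kind is ObsKind.CONCENTRATION and (o.blq or o.value < lloq):
                removed += 1
            else:
                kept.append(o)
        subjects.append(replace_subject(s, observations=kept))
    return BlqFilterResult(StudyDataset(subjects=subjects), removed)


def replace_subject(s: Subject, **changes) -> Subject:
    """Shallow-copy a subject with selected fields replaced."""
    kwargs = dict(
        id=s.id,
        site=s.site,
        covariates=dict(s.covariates),
        doses=list(s.doses),
        observations=list(s.observations),
    )
    kwargs.update(changes)
    return Subject(**kwargs)
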