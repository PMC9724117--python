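"""Canonical participant data model, cohort file I/O, phenotype derivation
and eligibility filtering.

Units are canonical throughout the cohort layer: lipids in mmol/L, blood
pressure in mmHg, age in years, CD4 in cells/mm^3, ART exposures in years.
Per-model unit conversion (e.g. mg/dL cholesterol for the Framingham and
pooled-cohort equations) happens inside the scoring engines, never here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantRecord",
    "RawMeasurements",
    "CohortTable",
    "ParseReport",
    "ExclusionReport",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "derive_phenotypes",
    "apply_eligibility",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the column mapping is incomplete."""


class ValidationError(ValueError):
    """Record-level invariant violation (e.g. duplicate ids)."""


SEX_VALUES = ("male", "female")
SMOKING_VALUES = ("current", "ex", "never")

#: canonical column order; (name, kind) with kind in {str, float, bool, cat}
_FIELDS: tuple[tuple[str, str], ...] = (
    ("id", "str"),
    ("age", "float"),
    ("sex", "cat"),
    ("sbp", "float"),
    ("dbp", "float"),
    ("bp_treated", "bool"),
    ("total_chol", "float"),
    ("hdl_chol", "float"),
    ("smoking", "cat"),
    ("diabetes", "bool"),
    ("hba1c", "float"),
    ("bmi", "float"),
    ("family_history_cvd", "bool"),
    ("on_art", "bool"),
    ("cd4_latest", "float"),
    ("exposure_years_pi_indinavir", "float"),
    ("exposure_years_pi_lopinavir", "float"),
    ("abacavir_current", "bool"),
    ("established_cvd", "bool"),
    ("bp_device_validated", "bool"),
    ("race", "cat"),
)

COLUMNS = tuple(name for name, _ in _FIELDS)
FLOAT_COLUMNS = tuple(n for n, k in _FIELDS if k == "float")
BOOL_COLUMNS = tuple(n for n, k in _FIELDS if k == "bool")

#: columns that may be absent from an input file without a schema error
_OPTIONAL = {"hba1c", "bmi", "cd4_latest", "bp_device_validated", "race", "dbp"}

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


@dataclass
class ParticipantRecord:
    """One participant's risk-factor and ART-exposure profile.

    ``sbp``/``dbp`` are nullable (``None``): missing blood pressure is routed
    to the imputation stage rather than rejected. ``hypertension`` and
    ``obesity`` are derived phenotypes, populated by
    :func:`derive_phenotypes`.
    """

    id: str
    age: float
    sex: str
    sbp: float | None
    dbp: float | None
    bp_treated: bool
    total_chol: float
    hdl_chol: float
    smoking: str
    diabetes: bool
    family_history_cvd: bool
    on_art: bool
    exposure_years_pi_indinavir: float = 0.0
    exposure_years_pi_lopinavir: float = 0.0
    abacavir_current: bool = False
    established_cvd: bool = False
    bp_device_validated: bool = True
    hba1c: float | None = None
    bmi: float | None = None
    cd4_latest: float | None = None
    race: str = "black"
    hypertension: bool | None = None
    obesity: bool | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEX_VALUES:
            raise ValidationError(f"sex must be one of {SEX_VALUES}, got {self.sex!r}")
        if self.smoking not in SMOKING_VALUES:
            raise ValidationError(
                f"smoking must be one of {SMOKING_VALUES}, got {self.smoking!r}"
            )
        if not self.age > 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        for name in ("sbp", "dbp"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive when present, got {v}")
        if not self.total_chol > 0 or not self.hdl_chol > 0:
            raise ValidationError("cholesterol values must be positive")
        if not self.hdl_chol < self.total_chol:
            raise ValidationError(
                f"hdl_chol ({self.hdl_chol}) must be below total_chol ({self.total_chol})"
            )
        for name in ("exposure_years_pi_indinavir", "exposure_years_pi_lopinavir"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.cd4_latest is not None and self.cd4_latest < 0:
            raise ValidationError("cd4_latest must be non-negative when present")


@dataclass
class RawMeasurements:
    """Raw clinic measurements feeding phenotype derivation.

    ``bp_readings`` holds up to three (systolic, diastolic) pairs in
    measurement order; the mean of readings 2 and 3 becomes the analysis BP.
    """

    bp_readings: Sequence[tuple[float, float]] = ()
    hba1c: float | None = None
    on_diabetes_medication: bool = False


@dataclass
class ParseReport:
    """Counts of cells coerced to null (or defaulted) while reading a file."""

    coerced_cells: int = 0
    defaulted_cells: int = 0
    by_column: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.coerced_cells + self.defaulted_cells

    def _tick(self, column: str, defaulted: bool = False) -> None:
        if defaulted:
            self.defaulted_cells += 1
        else:
            self.coerced_cells += 1
        self.by_column[column] = self.by_column.get(column, 0) + 1


@dataclass
class ExclusionReport:
    """Per-reason exclusion counts from the eligibility filter."""

    total_in: int = 0
    kept: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def excluded(self) -> int:
        return self.total_in - self.kept

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self) | {"excluded": self.excluded}, indent=2)


class CohortTable:
    """Ordered collection of participant records backed by a DataFrame.

    Ordering and all field values are stable under a write/read round-trip
    through :func:`write_cohort` / :func:`read_cohort`.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = ""):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"cohort frame lacks columns: {missing}")
        ids = frame["id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate participant ids: {sorted(set(dup))[:5]}")
        self.frame = frame.reset_index(drop=True)[list(COLUMNS)]
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records())

    def records(self) -> list[ParticipantRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            for col in FLOAT_COLUMNS:
                v = d[col]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    d[col] = None
            out.append(ParticipantRecord(**d))
        return out

    @classmethod
    def from_records(cls, records: Iterable[ParticipantRecord], provenance: str = "") -> "CohortTable":
        rows = []
        for r in records:
            d = dataclasses.asdict(r)
            d.pop("hypertension", None)
            d.pop("obesity", None)
            rows.append(d)
        frame = pd.DataFrame(rows, columns=list(COLUMNS))
        for col in FLOAT_COLUMNS:
            frame[col] = pd.to_numeric(frame[col], errors="coerce").astype(float)
        return cls(frame, provenance)

    def copy(self) -> "CohortTable":
        return CohortTable(self.frame.copy(), self.provenance)


def _parse_bool(raw: str, column: str, report: ParseReport, default: bool = False) -> bool:
    s = raw.strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    # blanks (e.g. unanswered established-CVD questions) default to False and
    # are surfaced through the parse report rather than silently dropped
    report._tick(column, defaulted=True)
    return default


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> tuple[CohortTable, ParseReport]:
    """Read a delimited cohort file into a :class:`CohortTable`.

    ``schema`` maps canonical field names to column names in the file
    (identity mapping by default). Unparseable numeric cells become nulls and
    are counted in the returned :class:`ParseReport`; a missing mandatory
    column raises :class:`SchemaError` naming the column.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = {f: f for f in COLUMNS}
    if schema:
        mapping.update(schema)

    report = ParseReport()
    data: dict[str, list] = {}
    n = len(raw)
    for canon in COLUMNS:
        src = mapping[canon]
        if src not in raw.columns:
            if canon in _OPTIONAL:
                if canon == "race":
                    data[canon] = ["black"] * n
                elif canon == "bp_device_validated":
                    data[canon] = [True] * n
                else:
                    data[canon] = [np.nan] * n
                continue
            raise SchemaError(f"missing mandatory column {src!r} (field {canon!r})")
        col = raw[src]
        kind = dict(_FIELDS)[canon]
        if kind == "float":
            vals = pd.to_numeric(col.str.strip(), errors="coerce")
            bad = vals.isna() & (col.str.strip() != "")
            for _ in range(int(bad.sum())):
                report._tick(canon)
            data[canon] = vals.astype(float).tolist()
        elif kind == "bool":
            data[canon] = [_parse_bool(v, canon, report) for v in col]
        else:
            data[canon] = [v.strip() for v in col]

    frame = pd.DataFrame(data, columns=list(COLUMNS))
    table = CohortTable(frame, provenance or str(path))
    return table, report


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the canonical CSV dialect (UTF-8, header row, lowercase booleans,
    empty string for nulls). Round-trips bit-for-bit through
    :func:`read_cohort`."""
    out = table.frame.copy()
    for col in BOOL_COLUMNS:
        out[col] = out[col].map(lambda b: "true" if b else "false")
    for col in FLOAT_COLUMNS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, encoding="utf-8")


def derive_phenotypes(
    record: ParticipantRecord,
    raw: RawMeasurements,
    hba1c_threshold: float = 6.5,
) -> ParticipantRecord:
    """Derive analysis blood pressure and clinical phenotypes from raw
    measurements.

    Analysis SBP/DBP is the mean of BP readings 2 and 3 (with exactly two
    readings, reading 2 alone); fewer than two readings leaves BP null for
    the imputation stage. Diabetes is HbA1c strictly above ``hba1c_threshold``
    or diabetes medication. Hypertension is BP >= 140/90 or BP-lowering
    treatment; obesity is BMI > 30 kg/m^2.
    """
    updates: dict = {}
    readings = list(raw.bp_readings)
    if len(readings) >= 2:
        tail = readings[1:3]
        updates["sbp"] = float(np.mean([s for s, _ in tail]))
        updates["dbp"] = float(np.mean([d for _, d in tail]))
    else:
        updates["sbp"] = None
        updates["dbp"] = None

    if raw.hba1c is not None:
        updates["hba1c"] = float(raw.hba1c)
    hba1c = updates.get("hba1c", record.hba1c)
    diabetic = raw.on_diabetes_medication or (hba1c is not None and hba1c > hba1c_threshold)
    updates["diabetes"] = bool(diabetic)

    sbp, dbp = updates["sbp"], updates["dbp"]
    if sbp is None:
        updates["hypertension"] = True if record.bp_treated else None
    else:
        updates["hypertension"] = bool(sbp >= 140 or (dbp or 0) >= 90 or record.bp_treated)
    updates["obesity"] = None if record.bmi is None else bool(record.bmi > 30)
    return dataclasses.replace(record, **updates)


def apply_eligibility(
    table: CohortTable,
    age_min: float = 30.0,
    age_max: float = 75.0,
) -> tuple[CohortTable, ExclusionReport]:
    """Retain participants aged ``age_min``..``age_max`` inclusive and without
    established CVD; count each exclusion reason (first matching reason per
    record, in the order below)."""
    f = table.frame
    report = ExclusionReport(total_in=len(f))
    below = f["age"] < age_min
    above = f["age"] > age_max
    cvd = f["established_cvd"].astype(bool) & ~below & ~above
    for reason, mask in (
        (f"age below {age_min:g}", below),
        (f"age above {age_max:g}", above),
        ("established CVD", cvd),
    ):
        k = int(mask.sum())
        if k:
            report.reasons[reason] = k
    keep = ~(below | above) & ~f["established_cvd"].astype(bool)
    kept = CohortTable(f[keep].reset_index(drop=True), table.provenance)
    report.kept = len(kept)
    return kept, report
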