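"""Domain model for ground-glass nodule screening cohorts.

A :class:`Cohort` holds patients and their pure ground-glass nodules (pGGNs)
together with the imaging attributes the risk-stratification rules consume:
the mean axial diameter in millimetres, the GGN-vessel-relationship type
(GVR I-IV, describing how pulmonary vessels relate to the nodule), an
"other suspicious malignant imaging features" flag, and the pathology ground
truth (invasive = minimally invasive or invasive adenocarcinoma; noninvasive
= benign, inflammatory, or adenomatous precursor lesions).

Cohorts round-trip through flat CSV (one row per nodule, patient attributes
repeated) and a JSON mirror with separate patient and nodule arrays.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Any, Iterable, Union

import pandas as pd

from .errors import RowError, SchemaError, ValidationError

__all__ = [
    "GVRType",
    "Category",
    "Nodule",
    "Patient",
    "Cohort",
    "mean_diameter",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]


class GVRType(enum.IntEnum):
    """GGN-vessel relationship type.

    I: vessels pass beside the nodule; II: vessels pass through without
    thickening or distortion; III: vessels pass through with localised
    thickening; IV: increased, thickened, twisted and convoluted vessels.
    The integer value orders the types I < II < III < IV for reporting.
    """

    I = 1
    II = 2
    III = 3
    IV = 4

    def __str__(self) -> str:  # serialized as roman numerals
        return self.name

    @classmethod
    def parse(cls, token: object) -> "GVRType":
        """Parse a GVR token case-insensitively from {I..IV, 1..4}."""
        if isinstance(token, GVRType):
            return token
        if isinstance(token, (int, float)) and not isinstance(token, bool):
            if float(token).is_integer() and 1 <= int(token) <= 4:
                return cls(int(token))
            raise ValidationError(f"gvr: {token!r} is not a valid GVR type")
        text = str(token).strip().upper()
        roman = {"I": 1, "II": 2, "III": 3, "IV": 4, "1": 1, "2": 2, "3": 3, "4": 4}
        if text in roman:
            return cls(roman[text])
        raise ValidationError(f"gvr: {token!r} is not a valid GVR type")


class Category(enum.Enum):
    """Ordinal risk category shared by all three rule sets.

    ``ordinal_rank`` (2 -> 1, 3 -> 2, 4a -> 3, 4b -> 4, 4x -> 5) is the
    score used when a system's output is treated as an ordinal classifier
    for ROC analysis.
    """

    C2 = "2"
    C3 = "3"
    C4A = "4a"
    C4B = "4b"
    C4X = "4x"

    @property
    def ordinal_rank(self) -> int:
        return {"2": 1, "3": 2, "4a": 3, "4b": 4, "4x": 5}[self.value]

    def __str__(self) -> str:
        return self.value

    @classmethod
    def parse(cls, token: object) -> "Category":
        if isinstance(token, Category):
            return token
        text = str(token).strip().lower()
        for member in cls:
            if member.value == text:
                return member
        raise ValidationError(f"category: {token!r} not one of 2/3/4a/4b/4x")

    def __lt__(self, other: "Category") -> bool:
        return self.ordinal_rank < other.ordinal_rank


def mean_diameter(long_axis_mm: float, short_axis_mm: float) -> float:
    """Mean nodule diameter: average of the maximum axial diameter and its
    perpendicular minor diameter, in mm. No rounding is applied."""
    for name, value in (("long_axis_mm", long_axis_mm), ("short_axis_mm", short_axis_mm)):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValidationError(f"{name}: expected a number, got {value!r}")
        if not math.isfinite(value):
            raise ValidationError(f"{name}: must be finite, got {value!r}")
        if value <= 0:
            raise ValidationError(f"{name}: must be > 0, got {value!r}")
    if short_axis_mm > long_axis_mm:
        raise ValidationError(
            f"short_axis_mm ({short_axis_mm}) exceeds long_axis_mm ({long_axis_mm})"
        )
    return (float(long_axis_mm) + float(short_axis_mm)) / 2.0


def _check_positive(name: str, value: float) -> float:
    if value is None or not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name}: must be positive and finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class Nodule:
    """One pGGN with its imaging attributes and optional pathology label."""

    nodule_id: str
    patient_id: str
    mean_diameter_mm: float
    long_axis_mm: float | None = None
    short_axis_mm: float | None = None
    gvr: GVRType | None = None
    suspicious_features: bool = False
    border: str | None = None  # blurry | clear | sharp
    pathology: str | None = None  # invasive | noninvasive
    extras: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        _check_positive("mean_diameter_mm", self.mean_diameter_mm)
        if (self.long_axis_mm is None) != (self.short_axis_mm is None):
            raise ValidationError(
                f"nodule {self.nodule_id}: provide both axes or neither"
            )
        if self.long_axis_mm is not None:
            implied = mean_diameter(self.long_axis_mm, self.short_axis_mm)
            if not math.isclose(implied, self.mean_diameter_mm, rel_tol=0, abs_tol=1e-9):
                raise ValidationError(
                    f"nodule {self.nodule_id}: mean_diameter_mm "
                    f"{self.mean_diameter_mm} != (long+short)/2 = {implied}"
                )
        if self.border is not None and self.border not in ("blurry", "clear", "sharp"):
            raise ValidationError(
                f"nodule {self.nodule_id}: border {self.border!r} "
                "not one of blurry/clear/sharp"
            )
        if self.pathology is not None and self.pathology not in ("invasive", "noninvasive"):
            raise ValidationError(
                f"nodule {self.nodule_id}: pathology {self.pathology!r} "
                "not one of invasive/noninvasive"
            )

    @property
    def invasive(self) -> bool | None:
        if self.pathology is None:
            return None
        return self.pathology == "invasive"


@dataclass(frozen=True)
class Patient:
    patient_id: str
    age_years: float | None = None
    sex: str | None = None  # male | female
    followup_months: float | None = None
    nodule_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.age_years is not None:
            _check_positive("age_years", self.age_years)
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValidationError(
                f"patient {self.patient_id}: sex {self.sex!r} not male/female"
            )
        if self.followup_months is not None and self.followup_months < 0:
            raise ValidationError(
                f"patient {self.patient_id}: followup_months must be >= 0"
            )


@dataclass
class Cohort:
    """A validated collection of patients and their nodules."""

    patients: list[Patient]
    nodules: list[Nodule]
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nodule_ids = [n.nodule_id for n in self.nodules]
        if len(set(nodule_ids)) != len(nodule_ids):
            dupes = sorted({i for i in nodule_ids if nodule_ids.count(i) > 1})
            raise ValidationError(f"duplicate nodule ids: {dupes}")
        patient_ids = [p.patient_id for p in self.patients]
        if len(set(patient_ids)) != len(patient_ids):
            raise ValidationError("duplicate patient ids")
        known = set(patient_ids)
        for n in self.nodules:
            if n.patient_id not in known:
                raise ValidationError(
                    f"nodule {n.nodule_id}: unknown patient_id {n.patient_id!r}"
                )

    def __len__(self) -> int:
        return len(self.nodules)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def with_label(self, label: str) -> "Cohort":
        return Cohort(self.patients, self.nodules, label=label)


# Flat per-nodule table schema (exact column order for CSV output).
COHORT_COLUMNS = [
    "patient_id",
    "nodule_id",
    "age_years",
    "sex",
    "long_axis_mm",
    "short_axis_mm",
    "mean_diameter_mm",
    "gvr",
    "suspicious_features",
    "border",
    "pathology",
    "followup_months",
]

_REQUIRED = ["patient_id", "nodule_id", "gvr", "suspicious_features", "pathology"]


def _parse_bool(token: object, row: int, column: str) -> bool:
    if isinstance(token, bool):
        return token
    text = str(token).strip().lower()
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f"):
        return False
    raise RowError(f"{column}: cannot parse boolean from {token!r}", row)


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _float_or_none(value: object, row: int, column: str) -> float | None:
    if _is_missing(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(f"{column}: cannot parse number from {value!r}", row) from None


def _rows_to_cohort(df: pd.DataFrame, label: str) -> Cohort:
    missing = [c for c in _REQUIRED if c not in df.columns]
    has_mean = "mean_diameter_mm" in df.columns
    has_axes = "long_axis_mm" in df.columns and "short_axis_mm" in df.columns
    if not (has_mean or has_axes):
        missing.append("mean_diameter_mm")
    if missing:
        raise SchemaError(
            f"cohort table is missing required column(s): {', '.join(missing)}",
            missing=missing,
        )
    extras_cols = [c for c in df.columns if c not in COHORT_COLUMNS]

    nodules: list[Nodule] = []
    patients: dict[str, Patient] = {}
    patient_nodules: dict[str, list[str]] = {}
    for idx, rec in enumerate(df.to_dict("records")):
        long_axis = _float_or_none(rec.get("long_axis_mm"), idx, "long_axis_mm")
        short_axis = _float_or_none(rec.get("short_axis_mm"), idx, "short_axis_mm")
        mean_mm = _float_or_none(rec.get("mean_diameter_mm"), idx, "mean_diameter_mm")
        if mean_mm is None:
            if long_axis is None or short_axis is None:
                raise RowError("no mean_diameter_mm and axes incomplete", idx)
            mean_mm = mean_diameter(long_axis, short_axis)

        gvr_token = rec.get("gvr")
        try:
            gvr = None if _is_missing(gvr_token) else GVRType.parse(gvr_token)
        except ValidationError as exc:
            raise RowError(str(exc), idx) from None

        susp_token = rec.get("suspicious_features")
        if _is_missing(susp_token):
            warnings.warn(
                f"row {idx}: suspicious_features missing; treated as false",
                stacklevel=2,
            )
            suspicious = False
        else:
            suspicious = _parse_bool(susp_token, idx, "suspicious_features")

        path_token = rec.get("pathology")
        if _is_missing(path_token):
            pathology = None
        else:
            pathology = str(path_token).strip().lower()
            if pathology not in ("invasive", "noninvasive"):
                raise RowError(
                    f"pathology: {path_token!r} not invasive/noninvasive", idx
                )

        border_token = rec.get("border")
        border = None if _is_missing(border_token) else str(border_token).strip().lower()

        extras = {c: rec[c] for c in extras_cols if not _is_missing(rec.get(c))}
        try:
            nodule = Nodule(
                nodule_id=str(rec["nodule_id"]),
                patient_id=str(rec["patient_id"]),
                mean_diameter_mm=mean_mm,
                long_axis_mm=long_axis,
                short_axis_mm=short_axis,
                gvr=gvr,
                suspicious_features=suspicious,
                border=border,
                pathology=pathology,
                extras=extras,
            )
        except ValidationError as exc:
            raise RowError(str(exc), idx) from None
        nodules.append(nodule)

        pid = nodule.patient_id
        patient_nodules.setdefault(pid, []).append(nodule.nodule_id)
        if pid not in patients:
            sex_token = rec.get("sex")
            sex = None if _is_missing(sex_token) else str(sex_token).strip().lower()
            patients[pid] = Patient(
                patient_id=pid,
                age_years=_float_or_none(rec.get("age_years"), idx, "age_years"),
                sex=sex,
                followup_months=_float_or_none(
                    rec.get("followup_months"), idx, "followup_months"
                ),
            )

    patient_list = [
        replace(p, nodule_ids=tuple(patient_nodules[pid]))
        for pid, p in patients.items()
    ]
    return Cohort(patients=patient_list, nodules=nodules, label=label)


def _cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    by_pid = {p.patient_id: p for p in cohort.patients}
    rows = []
    for n in cohort.nodules:
        p = by_pid[n.patient_id]
        rows.append(
            {
                "patient_id": n.patient_id,
                "nodule_id": n.nodule_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "long_axis_mm": n.long_axis_mm,
                "short_axis_mm": n.short_axis_mm,
                "mean_diameter_mm": n.mean_diameter_mm,
                "gvr": None if n.gvr is None else str(n.gvr),
                "suspicious_features": "true" if n.suspicious_features else "false",
                "border": n.border,
                "pathology": n.pathology,
                "followup_months": p.followup_months,
                **n.extras,
            }
        )
    extras_cols = sorted({k for r in rows for k in r} - set(COHORT_COLUMNS))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS + extras_cols)


Source = Union[str, Path, IO[str]]


def _infer_format(source: Source, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"format must be csv or json, got {fmt!r}")
        return fmt
    if isinstance(source, (str, Path)):
        suffix = Path(source).suffix.lower()
        if suffix == ".json":
            return "json"
        if suffix == ".csv":
            return "csv"
    return "csv"


def read_cohort(source: Source, format: str | None = None, label: str = "") -> Cohort:
    """Read a cohort from CSV (flat per-nodule table) or JSON.

    Required columns: patient_id, nodule_id, gvr, suspicious_features,
    pathology, and either mean_diameter_mm or both axis columns. Unknown
    columns are preserved per nodule in ``Nodule.extras``.
    """
    fmt = _infer_format(source, format)
    if fmt == "csv":
        try:
            df = pd.read_csv(source, dtype=str)
        except pd.errors.EmptyDataError:
            raise SchemaError("empty CSV: no header row") from None
        if df.empty and not set(_REQUIRED) <= set(df.columns):
            raise SchemaError(
                "cohort table is missing required column(s): "
                + ", ".join(c for c in _REQUIRED if c not in df.columns),
                missing=[c for c in _REQUIRED if c not in df.columns],
            )
        return _rows_to_cohort(df, label)

    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    else:
        doc = json.load(source)
    if not isinstance(doc, dict) or "nodules" not in doc:
        raise SchemaError("JSON cohort must be an object with a 'nodules' array")
    patient_meta = {p["patient_id"]: p for p in doc.get("patients", [])}
    rows = []
    for nod in doc["nodules"]:
        row = dict(nod)
        row.update(row.pop("extras", {}))
        meta = patient_meta.get(nod.get("patient_id"), {})
        for key in ("age_years", "sex", "followup_months"):
            row.setdefault(key, meta.get(key))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=COHORT_COLUMNS)
    return _rows_to_cohort(df, doc.get("label", label) or label)


def write_cohort(cohort: Cohort, sink: Source, format: str | None = None) -> None:
    """Write a cohort as UTF-8 CSV (deterministic column order) or JSON."""
    fmt = _infer_format(sink, format)
    if fmt == "csv":
        df = _cohort_to_frame(cohort)
        df.to_csv(sink, index=False)
        return
    doc = {
        "label": cohort.label,
        "patients": [
            {
                "patient_id": p.patient_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "followup_months": p.followup_months,
                "nodule_ids": list(p.nodule_ids),
            }
            for p in cohort.patients
        ],
        "nodules": [
            {
                "nodule_id": n.nodule_id,
                "patient_id": n.patient_id,
                "long_axis_mm": n.long_axis_mm,
                "short_axis_mm": n.short_axis_mm,
                "mean_diameter_mm": n.mean_diameter_mm,
                "gvr": None if n.gvr is None else str(n.gvr),
                "suspicious_features": n.suspicious_features,
                "border": n.border,
                "pathology": n.pathology,
                **({"extras": n.extras} if n.extras else {}),
            }
            for n in cohort.nodules
        ],
    }
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
    else:
        json.dump(doc, sink, indent=1)


def cohort_from_nodules(
    nodules: Iterable[Nodule],
    label: str = "",
    patients: Iterable[Patient] | None = None,
) -> Cohort:
    """Build a cohort, synthesizing one bare Patient per distinct patient_id
    when no patient metadata is supplied."""
    nodule_list = list(nodules)
    if patients is None:
        groups: dict[str, list[str]] = {}
        for n in nodule_list:
            groups.setdefault(n.patient_id, []).append(n.nodule_id)
        patients = [
            Patient(patient_id=pid, nodule_ids=tuple(ids))
            for pid, ids in groups.items()
        ]
    return Cohort(patients=list(patients), nodules=nodule_list, label=label)
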