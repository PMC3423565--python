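"""Core domain types and record I/O.

The unit conventions follow Japanese hepatology practice: prothrombin time
(PT) is expressed as a percentage of a standardized value (lower is worse),
the INR is carried as a separate field and is never derived from PT%, total
and direct bilirubin are in mg/dL, and platelet counts are in units of
10^4/uL.  Intervals are whole days counted inclusively from the calendar day
of first disease symptoms, so "within 10 days" means an interval <= 10.

Missing values are encoded as empty CSV cells / JSON nulls and are never
imputed; each operation documents its own missing-data behaviour.
"""

from __future__ import annotations

import csv
import io
import json
import math
import os
from dataclasses import dataclass, field, fields, replace
from enum import Enum, IntEnum
from pathlib import Path
from typing import Any, Iterable, Sequence

from .errors import MissingDataError, ParseError, ValidationError

__all__ = [
    "ComaGrade",
    "Etiology",
    "ViralSub",
    "DrugSub",
    "EtiologyCode",
    "Treatment",
    "Outcome",
    "LabPanel",
    "PatientRecord",
    "load_records",
    "write_records",
    "CSV_COLUMNS",
]


class ComaGrade(IntEnum):
    """Ordinal hepatic-encephalopathy grade (Inuyama 1972 scale).

    NONE < I < II < III < IV < V; grade >= II marks "hepatic coma" in the
    diagnostic criteria.
    """

    NONE = 0
    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5

    @classmethod
    def parse(cls, text: str) -> "ComaGrade":
        key = text.strip().upper()
        aliases = {"0": "NONE", "NONE": "NONE", "1": "I", "2": "II",
                   "3": "III", "4": "IV", "5": "V"}
        key = aliases.get(key, key)
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown coma grade {text!r}") from None

    def __str__(self) -> str:  # "none", "I".."V" in files
        return "none" if self is ComaGrade.NONE else self.name


class Etiology(str, Enum):
    """Major etiology classes of acute liver failure (2002 taxonomy, as
    modified in 2011).

    Classes I (viral), II (autoimmune) and III-1 (drug allergy) are
    hepatitis-compatible: such patients carry the additional diagnosis of
    fulminant hepatitis.  Classes III-2 (drug toxicity) and IV-VIII lack
    histological hepatitis.  IX is indeterminate despite sufficient work-up;
    X is unclassified for lack of examinations.
    """

    I_VIRAL = "I_viral"
    II_AUTOIMMUNE = "II_autoimmune"
    III_DRUG = "III_drug"
    IV_CIRCULATORY = "IV_circulatory"
    V_MALIGNANT_INFILTRATION = "V_malignant_infiltration"
    VI_METABOLIC = "VI_metabolic"
    VII_POST_RESECTION_TRANSPLANT = "VII_post_resection_transplant"
    VIII_MISCELLANEOUS = "VIII_miscellaneous"
    IX_INDETERMINATE = "IX_indeterminate"
    X_UNCLASSIFIED = "X_unclassified"


class ViralSub(str, Enum):
    HAV = "HAV"
    HBV_TRANSIENT = "HBV_transient"
    HBV_CARRIER_INACTIVE = "HBV_carrier_inactive"
    HBV_REACTIVATION_CARRIER = "HBV_reactivation_carrier"
    HBV_DE_NOVO = "HBV_de_novo"
    HBV_INDETERMINATE = "HBV_indeterminate"
    HCV = "HCV"
    HEV = "HEV"
    OTHER = "other"


class DrugSub(str, Enum):
    ALLERGY = "allergy"
    TOXICITY = "toxicity"


@dataclass(frozen=True)
class EtiologyCode:
    """Etiology assignment: a major class plus an optional subtype.

    ``viral_sub`` is only meaningful for class I and ``drug_sub`` only for
    class III; supplying either elsewhere is a validation error.
    """

    major: Etiology
    viral_sub: ViralSub | None = None
    drug_sub: DrugSub | None = None

    def validate(self, *, patient_id: str | None = None, row: int | None = None) -> None:
        if self.viral_sub is not None and self.major is not Etiology.I_VIRAL:
            raise ValidationError(
                "viral_sub only valid for etiology I (viral)",
                field="viral_sub", patient_id=patient_id, row=row)
        if self.drug_sub is not None and self.major is not Etiology.III_DRUG:
            raise ValidationError(
                "drug_sub only valid for etiology III (drug)",
                field="drug_sub", patient_id=patient_id, row=row)


class Treatment(str, Enum):
    MEDICAL_ONLY = "medical_only"
    TRANSPLANT = "transplant"


class Outcome(str, Enum):
    SURVIVED = "survived"
    DIED = "died"
    TRANSPLANTED_ALIVE = "transplanted_alive"
    TRANSPLANTED_DEAD = "transplanted_dead"

    @property
    def alive(self) -> bool:
        return self in (Outcome.SURVIVED, Outcome.TRANSPLANTED_ALIVE)


@dataclass(frozen=True)
class LabPanel:
    """Laboratory panel for one patient at the qualifying time point.

    At least one of ``pt_percent`` / ``inr`` must be present for a record to
    enter classification.  ``dt_ratio`` (direct/total bilirubin) is derived,
    never stored: it is defined only when both bilirubins are present and
    total > 0.
    """

    pt_percent: float | None = None
    inr: float | None = None
    total_bilirubin: float | None = None
    direct_bilirubin: float | None = None
    platelets: float | None = None

    @property
    def dt_ratio(self) -> float | None:
        if self.total_bilirubin is None or self.direct_bilirubin is None:
            return None
        if self.total_bilirubin <= 0:
            return None
        return self.direct_bilirubin / self.total_bilirubin

    def validate(self, *, patient_id: str | None = None, row: int | None = None) -> None:
        def bad(msg: str, fld: str) -> ValidationError:
            return ValidationError(msg, field=fld, patient_id=patient_id, row=row)

        if self.pt_percent is None and self.inr is None:
            raise bad("at least one of pt_percent / inr is required", "pt_percent")
        if self.pt_percent is not None and not (0 <= self.pt_percent <= 150):
            raise bad(f"pt_percent {self.pt_percent} outside [0, 150]", "pt_percent")
        if self.inr is not None and self.inr <= 0:
            raise bad(f"inr {self.inr} must be > 0", "inr")
        for fld in ("total_bilirubin", "direct_bilirubin", "platelets"):
            v = getattr(self, fld)
            if v is not None and (v < 0 or not math.isfinite(v)):
                raise bad(f"{fld} {v} must be a finite value >= 0", fld)
        if (self.total_bilirubin is not None and self.direct_bilirubin is not None
                and self.direct_bilirubin > self.total_bilirubin):
            raise bad(
                f"direct>total: direct_bilirubin {self.direct_bilirubin} exceeds "
                f"total_bilirubin {self.total_bilirubin}", "direct_bilirubin")


@dataclass
class PatientRecord:
    """One patient: demographics, intervals, labs, coma assessment,
    etiology, treatment arm and outcome.

    ``onset_to_encephalopathy_days`` is the O-C interval: whole days from
    first disease symptoms to grade >= II encephalopathy, present exactly
    when the (resolved) coma grade is >= II.  ``onset_to_labs_weeks`` is the
    time after symptom onset at which the qualifying laboratory values were
    obtained.  The coma assessment may be given as a grade, as structured
    clinical-feature flags, or both (in which case they must agree).
    """

    patient_id: str
    age_years: int
    labs: LabPanel
    etiology: EtiologyCode
    is_pediatric: bool = False
    onset_to_encephalopathy_days: int | None = None
    onset_to_labs_weeks: float | None = None
    liver_atrophy: bool | None = None
    coma_grade: ComaGrade | None = None
    coma_features: Any | None = None  # ClinicalFeatures | PediatricFeatures
    prior_liver_function_normal: bool = True
    habitual_alcohol_as_cause: bool = False
    treatment: Treatment = Treatment.MEDICAL_ONLY
    outcome: Outcome | None = None

    # -- coma resolution ---------------------------------------------------

    def resolved_coma_grade(self) -> ComaGrade:
        """The coma grade, taken directly or derived from feature flags."""
        if self.coma_grade is not None:
            return self.coma_grade
        if self.coma_features is not None:
            from .grading import grade_coma, grade_coma_pediatric, PediatricFeatures
            if isinstance(self.coma_features, PediatricFeatures):
                return grade_coma_pediatric(self.coma_features)
            return grade_coma(self.coma_features)
        raise MissingDataError("coma grade is neither given nor derivable",
                               missing=["coma_grade", "coma_features"],
                               patient_id=self.patient_id)

    # -- validation --------------------------------------------------------

    def validate(self, *, row: int | None = None) -> None:
        pid = self.patient_id
        if not pid:
            raise ValidationError("patient_id must be non-empty", field="patient_id", row=row)
        if self.age_years < 0:
            raise ValidationError(f"age_years {self.age_years} must be >= 0",
                                  field="age_years", patient_id=pid, row=row)
        self.labs.validate(patient_id=pid, row=row)
        self.etiology.validate(patient_id=pid, row=row)

        if self.coma_grade is None and self.coma_features is None:
            raise ValidationError(
                "at most one of coma_grade / coma_features may be missing",
                field="coma_grade", patient_id=pid, row=row)
        if self.coma_grade is not None and self.coma_features is not None:
            derived = replace(self, coma_grade=None).resolved_coma_grade()
            if derived is not self.coma_grade:
                raise ValidationError(
                    f"coma_grade {self.coma_grade} disagrees with grade "
                    f"{derived} derived from coma_features",
                    field="coma_grade", patient_id=pid, row=row)

        grade = self.resolved_coma_grade()
        if grade >= ComaGrade.II and self.onset_to_encephalopathy_days is None:
            raise ValidationError(
                "onset_to_encephalopathy_days required when coma grade >= II",
                field="onset_to_encephalopathy_days", patient_id=pid, row=row)
        if grade < ComaGrade.II and self.onset_to_encephalopathy_days is not None:
            raise ValidationError(
                "onset_to_encephalopathy_days only meaningful when coma grade >= II",
                field="onset_to_encephalopathy_days", patient_id=pid, row=row)
        if self.onset_to_encephalopathy_days is not None and self.onset_to_encephalopathy_days < 0:
            raise ValidationError("onset_to_encephalopathy_days must be >= 0",
                                  field="onset_to_encephalopathy_days",
                                  patient_id=pid, row=row)
        if self.onset_to_labs_weeks is not None and self.onset_to_labs_weeks < 0:
            raise ValidationError("onset_to_labs_weeks must be >= 0",
                                  field="onset_to_labs_weeks", patient_id=pid, row=row)
        if self.outcome is not None:
            transplanted = self.outcome in (Outcome.TRANSPLANTED_ALIVE,
                                            Outcome.TRANSPLANTED_DEAD)
            if transplanted != (self.treatment is Treatment.TRANSPLANT):
                raise ValidationError(
                    f"outcome {self.outcome.value} inconsistent with treatment "
                    f"{self.treatment.value}", field="outcome",
                    patient_id=pid, row=row)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS: tuple[str, ...] = (
    "patient_id", "age_years", "is_pediatric",
    "onset_to_encephalopathy_days", "onset_to_labs_weeks",
    "pt_percent", "inr", "total_bilirubin", "direct_bilirubin", "platelets",
    "liver_atrophy", "coma_grade", "etiology", "viral_sub", "drug_sub",
    "prior_liver_function_normal", "habitual_alcohol_as_cause",
    "treatment", "outcome",
)

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _parse_bool(text: str, fld: str) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise ValueError(f"{fld}: cannot parse boolean {text!r}") from None


def _opt(text: str | None) -> str | None:
    if text is None:
        return None
    text = text.strip()
    return text or None


def _record_from_strings(raw: dict[str, str | None], row: int) -> PatientRecord:
    def get(fld: str) -> str | None:
        return _opt(raw.get(fld))

    def req(fld: str) -> str:
        v = get(fld)
        if v is None:
            raise ValueError(f"{fld}: required value is missing")
        return v

    def fnum(fld: str) -> float | None:
        v = get(fld)
        return None if v is None else float(v)

    def inum(fld: str) -> int | None:
        v = get(fld)
        return None if v is None else int(v)

    def obool(fld: str, default: bool | None = None) -> bool | None:
        v = get(fld)
        return default if v is None else _parse_bool(v, fld)

    labs = LabPanel(
        pt_percent=fnum("pt_percent"),
        inr=fnum("inr"),
        total_bilirubin=fnum("total_bilirubin"),
        direct_bilirubin=fnum("direct_bilirubin"),
        platelets=fnum("platelets"),
    )
    et_major = Etiology(req("etiology"))
    vs = get("viral_sub")
    ds = get("drug_sub")
    etiology = EtiologyCode(
        major=et_major,
        viral_sub=ViralSub(vs) if vs else None,
        drug_sub=DrugSub(ds) if ds else None,
    )
    grade_text = get("coma_grade")
    treatment_text = get("treatment")
    outcome_text = get("outcome")
    return PatientRecord(
        patient_id=req("patient_id"),
        age_years=int(req("age_years")),
        is_pediatric=bool(obool("is_pediatric", default=False)),
        onset_to_encephalopathy_days=inum("onset_to_encephalopathy_days"),
        onset_to_labs_weeks=fnum("onset_to_labs_weeks"),
        labs=labs,
        liver_atrophy=obool("liver_atrophy"),
        coma_grade=ComaGrade.parse(grade_text) if grade_text else None,
        etiology=etiology,
        prior_liver_function_normal=bool(obool("prior_liver_function_normal", default=True)),
        habitual_alcohol_as_cause=bool(obool("habitual_alcohol_as_cause", default=False)),
        treatment=Treatment(treatment_text) if treatment_text else Treatment.MEDICAL_ONLY,
        outcome=Outcome(outcome_text) if outcome_text else None,
    )


def _features_from_json(obj: dict[str, Any], pediatric: bool) -> Any:
    from .grading import ClinicalFeatures, PediatricFeatures
    cls = PediatricFeatures if pediatric else ClinicalFeatures
    known = {f.name for f in fields(cls)}
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"unknown coma feature flags: {sorted(unknown)}")
    return cls(**{k: bool(v) for k, v in obj.items()})


def _record_from_json(obj: dict[str, Any], row: int) -> PatientRecord:
    raw = {k: (None if v is None else str(v)) for k, v in obj.items()
           if k != "coma_features"}
    rec = _record_from_strings(raw, row)
    feats = obj.get("coma_features")
    if feats is not None:
        rec.coma_features = _features_from_json(feats, rec.is_pediatric)
    return rec


def load_records(path: str | os.PathLike[str], format: str | None = None,
                 *, collect_errors: bool = False,
                 ) -> list[PatientRecord] | tuple[list[PatientRecord], list[ValidationError]]:
    """Load and validate patient records from CSV or JSON.

    ``format`` defaults to the file extension.  By default the first invalid
    row raises; with ``collect_errors=True`` a ``(records, errors)`` pair is
    returned where every error carries its data-row number and patient id.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("csv", "json"):
        raise ParseError(f"unsupported record format {format!r} for {path}")
    if not path.exists():
        raise ParseError(f"record file not found: {path}")

    records: list[PatientRecord] = []
    errors: list[ValidationError] = []

    def handle(rec_or_exc: PatientRecord | Exception, row: int) -> None:
        if isinstance(rec_or_exc, PatientRecord):
            try:
                rec_or_exc.validate(row=row)
                records.append(rec_or_exc)
                return
            except ValidationError as exc:
                err = exc
        elif isinstance(rec_or_exc, ValidationError):
            err = rec_or_exc
        else:
            err = ValidationError(str(rec_or_exc), row=row)
        if collect_errors:
            errors.append(err)
        else:
            raise err

    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ParseError(f"{path}: empty file, no header line")
            missing_cols = {"patient_id", "age_years", "etiology"} - set(reader.fieldnames)
            if missing_cols:
                raise ParseError(
                    f"{path}: line 1: missing required columns {sorted(missing_cols)}")
            for row, raw in enumerate(reader, start=1):
                try:
                    rec = _record_from_strings(raw, row)
                except (ValueError, KeyError) as exc:
                    handle(ValidationError(str(exc), row=row,
                                           patient_id=_opt(raw.get("patient_id"))), row)
                    continue
                handle(rec, row)
    else:
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from None
        if not isinstance(payload, list):
            raise ParseError(f"{path}: expected a JSON array of record objects")
        for row, obj in enumerate(payload, start=1):
            try:
                rec = _record_from_json(obj, row)
            except (ValueError, KeyError, TypeError) as exc:
                handle(ValidationError(str(exc), row=row,
                                       patient_id=str(obj.get("patient_id", "")) or None), row)
                continue
            handle(rec, row)

    if collect_errors:
        return records, errors
    return records


def _record_to_strings(rec: PatientRecord) -> dict[str, str]:
    def s(v: Any) -> str:
        if v is None:
            return ""
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, ComaGrade):
            return str(v)
        if isinstance(v, Enum):
            return v.value
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    return {
        "patient_id": rec.patient_id,
        "age_years": s(rec.age_years),
        "is_pediatric": s(rec.is_pediatric),
        "onset_to_encephalopathy_days": s(rec.onset_to_encephalopathy_days),
        "onset_to_labs_weeks": s(rec.onset_to_labs_weeks),
        "pt_percent": s(rec.labs.pt_percent),
        "inr": s(rec.labs.inr),
        "total_bilirubin": s(rec.labs.total_bilirubin),
        "direct_bilirubin": s(rec.labs.direct_bilirubin),
        "platelets": s(rec.labs.platelets),
        "liver_atrophy": s(rec.liver_atrophy),
        "coma_grade": s(rec.coma_grade),
        "etiology": s(rec.etiology.major),
        "viral_sub": s(rec.etiology.viral_sub),
        "drug_sub": s(rec.etiology.drug_sub),
        "prior_liver_function_normal": s(rec.prior_liver_function_normal),
        "habitual_alcohol_as_cause": s(rec.habitual_alcohol_as_cause),
        "treatment": s(rec.treatment),
        "outcome": s(rec.outcome),
    }


def write_records(records: Sequence[PatientRecord],
                  path: str | os.PathLike[str], format: str | None = None) -> None:
    """Write records as CSV or JSON (atomically: temp file then rename)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("csv", "json"):
        raise ParseError(f"unsupported record format {format!r} for {path}")

    if format == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(CSV_COLUMNS), lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_strings(rec))
        text = buf.getvalue()
    else:
        objs: list[dict[str, Any]] = []
        for rec in records:
            obj: dict[str, Any] = {}
            for k, v in _record_to_strings(rec).items():
                if v == "":
                    obj[k] = None
                elif k in ("age_years", "onset_to_encephalopathy_days"):
                    obj[k] = int(v)
                elif k in ("onset_to_labs_weeks", "pt_percent", "inr",
                           "total_bilirubin", "direct_bilirubin", "platelets"):
                    obj[k] = float(v)
                elif v in ("true", "false"):
                    obj[k] = v == "true"
                else:
                    obj[k] = v
            if rec.coma_features is not None:
                obj["coma_features"] = {
                    f.name: getattr(rec.coma_features, f.name)
                    for f in fields(rec.coma_features)
                    if getattr(rec.coma_features, f.name)
                }
            objs.append(obj)
        text = json.dumps(objs, indent=2) + "\n"

    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)
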