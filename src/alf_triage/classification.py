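"""Diagnostic classification under the 2011 Japanese acute-liver-failure
criteria.

A patient qualifies on the laboratory criterion when the prothrombin time is
40 % or less of the standardized value, or the INR is 1.5 or more.  ALF is
then split by encephalopathy: none/grade I within 8 weeks of symptom onset
is "ALF without hepatic coma"; grade >= II splits by the onset-to-
encephalopathy interval into the acute type (<= 10 days), the subacute type
(11-56 days), or — between 8 and 24 weeks (57-168 days, continuing the
day-based windows) — late-onset hepatic failure (LOHF), a related entity.

Patients with impaired liver function before the current insult, and
patients with alcoholic hepatitis (acute-on-chronic disease by nature), are
excluded.  Whether a patient additionally carries the diagnosis of
fulminant hepatitis depends only on the etiology class: viral infection,
autoimmune hepatitis and drug-allergy injury (I, II, III-1) are
hepatitis-compatible; drug toxicity and classes IV-VIII are not.  The two
residual classes have no printed rule and follow a configurable policy:
indeterminate-despite-work-up (IX) defaults to hepatitis-compatible, as
survey tallies count indeterminate etiology within the hepatitis group,
while unclassified-for-lack-of-examinations (X) defaults to not.

All thresholds live in :class:`ClassificationConfig`; the published values
are defaults, not hard-coded constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import ConfigError, MissingDataError
from .records import ComaGrade, Etiology, EtiologyCode, DrugSub, LabPanel, PatientRecord

__all__ = [
    "Category", "ExclusionReason", "DiagnosisResult", "ClassificationConfig",
    "meets_lab_criterion", "classify", "is_fulminant_hepatitis",
]


class Category(str, Enum):
    NOT_ALF = "NOT_ALF"
    ALF_WITHOUT_COMA = "ALF_WITHOUT_COMA"
    ALF_WITH_COMA_ACUTE = "ALF_WITH_COMA_ACUTE"
    ALF_WITH_COMA_SUBACUTE = "ALF_WITH_COMA_SUBACUTE"
    LOHF = "LOHF"


class ExclusionReason(str, Enum):
    LAB_CRITERION_NOT_MET = "lab_criterion_not_met"
    PRIOR_LIVER_DISEASE = "prior_liver_disease"
    ALCOHOLIC_HEPATITIS = "alcoholic_hepatitis"
    WINDOW_EXCEEDED = "window_exceeded"


@dataclass(frozen=True)
class DiagnosisResult:
    """Outcome of classification: the diagnostic category, the fulminant-
    hepatitis flag, the exclusion reason (present exactly when NOT_ALF), and
    the identifiers of the rules that fired."""

    category: Category
    fulminant_hepatitis: bool = False
    exclusion_reason: ExclusionReason | None = None
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.exclusion_reason is not None) != (self.category is Category.NOT_ALF):
            raise ValueError("exclusion_reason present iff category is NOT_ALF")
        if self.category is Category.NOT_ALF and self.fulminant_hepatitis:
            raise ValueError("fulminant_hepatitis must be false when NOT_ALF")


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the diagnostic criteria (published values as defaults).

    ``pt_max_percent``/``inr_min`` define the laboratory criterion;
    ``acute_max_days``/``subacute_max_days``/``lohf_max_days`` the interval
    windows (inclusive upper bounds); ``no_coma_max_weeks`` the qualifying-lab
    window for coma-free ALF.  ``indeterminate_is_hepatitis`` /
    ``unclassified_is_hepatitis`` set the fulminant-hepatitis policy for
    etiology classes IX and X.
    """

    pt_max_percent: float = 40.0
    inr_min: float = 1.5
    acute_max_days: int = 10
    subacute_max_days: int = 56
    lohf_max_days: int = 168
    no_coma_max_weeks: float = 8.0
    indeterminate_is_hepatitis: bool = True
    unclassified_is_hepatitis: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.pt_max_percent <= 150):
            raise ConfigError(f"pt_max_percent {self.pt_max_percent} outside (0, 150]")
        if self.inr_min <= 0:
            raise ConfigError(f"inr_min {self.inr_min} must be > 0")
        if not (0 <= self.acute_max_days < self.subacute_max_days < self.lohf_max_days):
            raise ConfigError(
                "interval windows must satisfy 0 <= acute < subacute < lohf "
                f"(got {self.acute_max_days}/{self.subacute_max_days}/{self.lohf_max_days})")
        if self.no_coma_max_weeks <= 0:
            raise ConfigError("no_coma_max_weeks must be > 0")


DEFAULT_CONFIG = ClassificationConfig()

_HEPATITIS_MAJORS = frozenset({Etiology.I_VIRAL, Etiology.II_AUTOIMMUNE})


def meets_lab_criterion(labs: LabPanel,
                        config: ClassificationConfig = DEFAULT_CONFIG) -> bool:
    """True iff PT% <= 40 or INR >= 1.5 (thresholds from ``config``).

    Either measurement alone suffices; both missing is a missing-data error.
    """
    if labs.pt_percent is None and labs.inr is None:
        raise MissingDataError("laboratory criterion needs pt_percent or inr",
                               missing=["pt_percent", "inr"])
    if labs.pt_percent is not None and labs.pt_percent <= config.pt_max_percent:
        return True
    if labs.inr is not None and labs.inr >= config.inr_min:
        return True
    return False


def is_fulminant_hepatitis(category: Category, etiology: EtiologyCode,
                           config: ClassificationConfig = DEFAULT_CONFIG) -> bool:
    """Whether an ALF/LOHF patient also carries the fulminant-hepatitis
    diagnosis, by etiology class (see module docstring for the IX/X policy).

    Defined only for patients inside the ALF/LOHF entity.
    """
    if category is Category.NOT_ALF:
        raise ValueError("fulminant hepatitis is undefined outside ALF/LOHF")
    major = etiology.major
    if major in _HEPATITIS_MAJORS:
        return True
    if major is Etiology.III_DRUG:
        return etiology.drug_sub is DrugSub.ALLERGY
    if major is Etiology.IX_INDETERMINATE:
        return config.indeterminate_is_hepatitis
    if major is Etiology.X_UNCLASSIFIED:
        return config.unclassified_is_hepatitis
    return False


def classify(record: PatientRecord,
             config: ClassificationConfig = DEFAULT_CONFIG) -> DiagnosisResult:
    """Classify one validated record under the 2011 criteria.

    Exclusions are checked first (laboratory criterion, prior liver disease,
    habitual alcohol as the cause); the remaining patients partition by coma
    grade and interval into exactly one category.  A grade >= II record with
    no onset-to-encephalopathy interval, or a coma-free record with no
    qualifying-lab time, is a missing-data error.
    """
    rationale: list[str] = []

    def excluded(reason: ExclusionReason, why: str) -> DiagnosisResult:
        rationale.append(why)
        return DiagnosisResult(Category.NOT_ALF, False, reason, tuple(rationale))

    if not meets_lab_criterion(record.labs, config):
        return excluded(ExclusionReason.LAB_CRITERION_NOT_MET,
                        f"lab: PT>{config.pt_max_percent}% and INR<{config.inr_min}")
    rationale.append(f"lab: PT<={config.pt_max_percent}% or INR>={config.inr_min}")

    if not record.prior_liver_function_normal:
        return excluded(ExclusionReason.PRIOR_LIVER_DISEASE,
                        "exclusion: prior liver function impaired")
    if record.habitual_alcohol_as_cause:
        return excluded(ExclusionReason.ALCOHOLIC_HEPATITIS,
                        "exclusion: alcoholic hepatitis (acute-on-chronic)")

    grade = record.resolved_coma_grade()
    if grade < ComaGrade.II:
        weeks = record.onset_to_labs_weeks
        if weeks is None:
            raise MissingDataError(
                "coma-free classification needs the qualifying-lab time",
                missing=["onset_to_labs_weeks"], patient_id=record.patient_id)
        if weeks > config.no_coma_max_weeks:
            return excluded(ExclusionReason.WINDOW_EXCEEDED,
                            f"window: labs at {weeks} wk > {config.no_coma_max_weeks} wk")
        rationale.append(f"coma: grade {grade} < II, labs within "
                         f"{config.no_coma_max_weeks} wk")
        category = Category.ALF_WITHOUT_COMA
    else:
        days = record.onset_to_encephalopathy_days
        if days is None:
            raise MissingDataError(
                "grade >= II encephalopathy needs the onset-to-encephalopathy interval",
                missing=["onset_to_encephalopathy_days"], patient_id=record.patient_id)
        if days <= config.acute_max_days:
            rationale.append(f"window: coma at {days} d <= {config.acute_max_days} d (acute)")
            category = Category.ALF_WITH_COMA_ACUTE
        elif days <= config.subacute_max_days:
            rationale.append(f"window: coma at {days} d in "
                             f"({config.acute_max_days}, {config.subacute_max_days}] d (subacute)")
            category = Category.ALF_WITH_COMA_SUBACUTE
        elif days <= config.lohf_max_days:
            rationale.append(f"window: coma at {days} d in "
                             f"({config.subacute_max_days}, {config.lohf_max_days}] d (LOHF)")
            category = Category.LOHF
        else:
            return excluded(ExclusionReason.WINDOW_EXCEEDED,
                            f"window: coma at {days} d > {config.lohf_max_days} d")

    fh = is_fulminant_hepatitis(category, record.etiology, config)
    rationale.append(
        f"etiology {record.etiology.major.value}: "
        f"{'hepatitis-compatible' if fh else 'not hepatitis-compatible'}")
    return DiagnosisResult(category, fh, None, tuple(rationale))
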